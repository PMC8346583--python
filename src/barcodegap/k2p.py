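"""Kimura 2-parameter distances between aligned sequences.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
For a sequence pair with transition proportion P and transversion proportion
Q over the compared sites, the distance in substitutions/site is

    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)

Sites where either sequence carries a gap, N or any IUPAC ambiguity code are
excluded pair-by-pair (pairwise deletion), so each pair has its own number of
compared sites.  Complete deletion (drop a column if ANY sequence is
ambiguous there) is available as an option.  When the log arguments are
non-positive the pair is saturated and the distance is undefined (NaN),
never clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import UsageError
from .seqio import AlignedLocus

logger = logging.getLogger("barcodegap")

# Purines first so that a transition is "same high bit, different low bit".
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_MISSING = 255


class PairStatus(Enum):
    OK = "ok"
    SATURATED = "saturated"
    NO_SITES = "no_sites"
    TOO_FEW_SITES = "too_few_sites"


@dataclass(frozen=True)
class SitePatternCounts:
    """Per-pair site tallies under pairwise deletion."""

    n_compared: int
    n_transition: int
    n_transversion: int

    def __post_init__(self) -> None:
        if min(self.n_compared, self.n_transition, self.n_transversion) < 0:
            raise UsageError("site-pattern counts must be non-negative")
        if self.n_transition + self.n_transversion > self.n_compared:
            raise UsageError("differences exceed compared sites")

    @property
    def p(self) -> float:
        """Transition proportion P."""
        return self.n_transition / self.n_compared

    @property
    def q(self) -> float:
        """Transversion proportion Q."""
        return self.n_transversion / self.n_compared


def encode(seq: str) -> np.ndarray:
    """Map A/G/C/T to 0..3 and every other symbol to a missing sentinel."""
    table = np.full(256, _MISSING, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_site_patterns(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> SitePatternCounts:
    """Count compared sites, transitions and transversions for one pair.

    Any site where either sequence is outside {A,C,G,T} is excluded from
    all three counts.
    """
    a = encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode(seq_b) if isinstance(seq_b, str) else seq_b
    if len(a) != len(b):
        raise UsageError(f"sequences have unequal lengths {len(a)} and {len(b)}")
    valid = (a != _MISSING) & (b != _MISSING)
    diff = valid & (a != b)
    transition = diff & ((a >> 1) == (b >> 1))
    n_diff = int(diff.sum())
    n_ts = int(transition.sum())
    return SitePatternCounts(int(valid.sum()), n_ts, n_diff - n_ts)


def k2p_distance(counts: SitePatternCounts) -> tuple[float, PairStatus]:
    """Evaluate the K2P closed form; NaN with a status on degenerate input.

    A pair with no comparable sites is flagged NO_SITES; a pair beyond the
    model's resolvable divergence (1-2P-Q <= 0 or 1-2Q <= 0) is SATURATED.
    """
    if counts.n_compared == 0:
        return math.nan, PairStatus.NO_SITES
    p, q = counts.p, counts.q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan, PairStatus.SATURATED
    # "+ 0.0" normalizes the IEEE negative zero that log(1) produces
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0, PairStatus.OK


class DistanceMatrix:
    """Symmetric pairwise distance matrix in substitutions/site.

    Undefined entries are NaN; ``n_sites`` records the per-pair number of
    compared sites and ``status`` why an entry is undefined.
    """

    def __init__(
        self,
        labels: list[str],
        data: np.ndarray,
        n_sites: np.ndarray | None = None,
        status: dict[tuple[int, int], PairStatus] | None = None,
    ):
        data = np.asarray(data, dtype=float)
        n = len(labels)
        if data.shape != (n, n):
            raise UsageError(f"matrix shape {data.shape} does not match {n} labels")
        if len(set(labels)) != n:
            raise UsageError("duplicate labels in distance matrix")
        if not np.allclose(np.nan_to_num(data), np.nan_to_num(data.T)):
            raise UsageError("distance matrix must be symmetric")
        if not np.all(np.diag(data) == 0.0):
            raise UsageError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.any(data[~np.isnan(data)] < 0):
                raise UsageError("distances must be non-negative")
        self.labels = list(labels)
        self.data = data
        self.n_sites = (
            np.asarray(n_sites, dtype=int) if n_sites is not None
            else np.zeros((n, n), dtype=int)
        )
        self.status = status or {}
        self._index = {lab: i for i, lab in enumerate(labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.data[self._index[a], self._index[b]])

    @property
    def is_complete(self) -> bool:
        """True when every off-diagonal entry is defined."""
        return not np.isnan(self.data).any()

    def n_undefined(self) -> int:
        n = len(self)
        iu = np.triu_indices(n, k=1)
        return int(np.isnan(self.data[iu]).sum())

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(labels, self.data[np.ix_(idx, idx)],
                              self.n_sites[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        """Square CSV with specimen ids as header row/column; NaN as "NA"."""
        self.to_dataframe().to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_phylip(self, path: str | Path, decimals: int = 6) -> None:
        """Lower-triangle PHYLIP-style text for interoperability."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for i, lab in enumerate(self.labels):
                cells = [
                    "NA" if math.isnan(self.data[i, j]) else f"{self.data[i, j]:.{decimals}f}"
                    for j in range(i)
                ]
                fh.write("\t".join([lab] + cells) + "\n")

    def to_skbio(self):
        """Convert to a scikit-bio DistanceMatrix (requires completeness)."""
        import skbio

        if not self.is_complete:
            raise UsageError("matrix has undefined entries; cannot convert")
        return skbio.DistanceMatrix(self.data, ids=self.labels)


def _complete_deletion_mask(encoded: list[np.ndarray]) -> np.ndarray:
    stacked = np.stack(encoded)
    return np.all(stacked != _MISSING, axis=0)


def pairwise_matrix(
    locus: AlignedLocus,
    min_sites: int = 100,
    deletion: Literal["pairwise", "complete"] = "pairwise",
) -> DistanceMatrix:
    """K2P distances between all specimen pairs of one locus.

    Pairs whose number of compared sites falls below ``min_sites`` are set
    undefined with a warning; this guards against distances estimated from
    tiny overlaps after truncation.
    """
    if len(locus) < 2:
        raise UsageError("pairwise_matrix needs >=2 records")
    if deletion not in ("pairwise", "complete"):
        raise UsageError(f"unknown deletion mode {deletion!r}")
    ids = locus.specimen_ids
    encoded = [encode(seq) for _, seq in locus.records]
    if deletion == "complete":
        keep = _complete_deletion_mask(encoded)
        encoded = [e[keep] for e in encoded]
    n = len(ids)
    data = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    status: dict[tuple[int, int], PairStatus] = {}
    for i in range(n):
        sites[i, i] = len(encoded[i])
        for j in range(i + 1, n):
            counts = count_site_patterns(encoded[i], encoded[j])
            d, st = k2p_distance(counts)
            if st is PairStatus.OK and counts.n_compared < min_sites:
                d, st = math.nan, PairStatus.TOO_FEW_SITES
                logger.warning(
                    "pair (%s, %s): only %d comparable sites (< min_sites=%d); "
                    "distance set to NA", ids[i], ids[j], counts.n_compared, min_sites,
                )
            elif st is not PairStatus.OK:
                logger.warning("pair (%s, %s): distance undefined (%s)",
                               ids[i], ids[j], st.value)
            data[i, j] = data[j, i] = d
            sites[i, j] = sites[j, i] = counts.n_compared
            if st is not PairStatus.OK:
                status[(i, j)] = st
    return DistanceMatrix(ids, data, sites, status)
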