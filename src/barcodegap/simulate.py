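"""Synthetic multi-locus barcode datasets and flow-cytometry event samples.

The sequence generator emulates a small herbarium barcoding study design: a
handful of species, a few specimens each, two or three short aligned loci.
Sequences evolve on a star species tree under the Kimura 2-parameter
substitution process — a root sequence drawn uniformly over {A,C,G,T}, one
ancestor per species at branch length (d_inter - d_intra)/2, and each
individual evolved a further d_intra/2 — so that by Markov additivity the
EXPECTED pairwise K2P distance is d_intra within species and d_inter between
species.  An optional overlap pair makes two species share one ancestor with
zero-length stems, reproducing the situation where two nominal species are
not genetically separated at all.  No indels are simulated, so the output is
trivially aligned.

The flow-cytometry generator draws fluorescence events from two normal
populations (sample and internal-reference nuclei) plus an optional
low-channel exponential debris component.

Default parameters mirror the emulated study: 10 species with 2–8 specimens
each (40 in total), loci of 641/730/750 aligned bp, intraspecific
divergence 0.002 and interspecific 0.01 substitutions/site, one overlapping
species pair, and one outgroup specimen; flow runs of >=10,000 nuclei in
triplicate with peak CVs around 5%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, UsageError
from .k2p import _CODE
from .seqio import AlignedLocus, SpecimenRecord

_BASES = np.array(["A", "G", "C", "T"])  # index order matches k2p encoding

#: Per-species specimen counts of the emulated study design (sum 40).
STUDY_COUNTS = (2, 2, 3, 8, 5, 5, 6, 3, 3, 3)
STUDY_LOCUS_LENGTHS = (641, 730, 750)
STUDY_LOCUS_NAMES = ("ITS", "matK", "trnL-trnF")


@dataclass
class SimConfig:
    """Design parameters of a synthetic barcoding dataset.

    ``d_intra`` and ``d_inter`` are expected pairwise K2P distances in
    substitutions/site; ``kappa`` is the transition/transversion rate ratio
    alpha/beta.  ``overlap_pair`` names two species (by index) that share an
    ancestor with zero-length stems, so their expected interspecific
    distance collapses to ``d_intra``.  ``d_outgroup`` adds one outgroup
    specimen at that expected distance from every ingroup root lineage.
    """

    n_species: int = 10
    n_per_species: int | tuple[int, ...] = STUDY_COUNTS
    locus_lengths: tuple[int, ...] = STUDY_LOCUS_LENGTHS
    locus_names: tuple[str, ...] = STUDY_LOCUS_NAMES
    d_intra: float = 0.002
    d_inter: float = 0.01
    kappa: float = 2.0
    overlap_pair: tuple[int, int] | None = (0, 1)
    d_outgroup: float | None = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.d_intra <= self.d_inter:
            raise ConfigError(
                f"need 0 <= d_intra <= d_inter, got {self.d_intra} > {self.d_inter}"
            )
        if self.kappa <= 0:
            raise ConfigError("kappa must be positive")
        if any(L <= 0 for L in self.locus_lengths):
            raise ConfigError("locus lengths must be positive")
        if len(self.locus_names) != len(self.locus_lengths):
            raise ConfigError("locus_names and locus_lengths must match")
        if isinstance(self.n_per_species, int):
            self.n_per_species = (self.n_per_species,) * self.n_species
        if len(self.n_per_species) != self.n_species:
            raise ConfigError("n_per_species must have one entry per species")
        if self.overlap_pair is not None:
            a, b = self.overlap_pair
            if not (0 <= a < self.n_species and 0 <= b < self.n_species and a != b):
                raise ConfigError(f"invalid overlap_pair {self.overlap_pair}")

    @property
    def species_names(self) -> list[str]:
        return [f"species_{i + 1:02d}" for i in range(self.n_species)]


def k2p_substitution_probs(d: float, kappa: float) -> tuple[float, float, float]:
    """Closed-form K2P substitution probabilities after distance ``d``.

    With beta*t = d/(kappa+2) and alpha*t = kappa*d/(kappa+2):

        P(transition)       = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta)t}
        P(any transversion) = 1/2 - 1/2 e^{-4 beta t}

    Returns (p_same, p_transition, p_transversion_total).
    """
    if d < 0:
        raise UsageError("distance must be non-negative")
    if kappa <= 0:
        raise UsageError("kappa must be positive")
    bt = d / (kappa + 2.0)
    at = kappa * d / (kappa + 2.0)
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    p_tv = 0.5 - 0.5 * math.exp(-4.0 * bt)
    return 1.0 - p_ts - p_tv, p_ts, p_tv


def evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Mutate an encoded sequence along a branch of expected length ``d``.

    Encoding: A=0, G=1, C=2, T=3 — the transition partner of base ``b`` is
    ``b ^ 1``; its transversion partners are ``b ^ 2`` and ``b ^ 3``.
    """
    if d == 0.0:
        return seq.copy()
    _, p_ts, p_tv = k2p_substitution_probs(d, kappa)
    u = rng.random(seq.shape)
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv / 2.0)
    tv2 = (u >= p_ts + p_tv / 2.0) & (u < p_ts + p_tv)
    out[ts] ^= 1
    out[tv1] ^= 2
    out[tv2] ^= 3
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _specimen_records(config: SimConfig) -> list[SpecimenRecord]:
    records = []
    for sp_idx, (name, count) in enumerate(zip(config.species_names, config.n_per_species)):
        # alternate native / non-native so both statuses occur in reports
        status = "native" if sp_idx % 2 == 0 else "non-native"
        for k in range(count):
            records.append(SpecimenRecord(f"sp{sp_idx + 1:02d}_ind{k + 1}", name, status))
    if config.d_outgroup is not None:
        records.append(SpecimenRecord("outgroup_1", "outgroup_taxon", "outgroup"))
    return records


def simulate_locus(
    config: SimConfig,
    length: int,
    rng: np.random.Generator,
    locus_name: str = "locus",
) -> AlignedLocus:
    """Simulate one aligned locus under the star-tree K2P design.

    The stem to each species ancestor has expected length
    (d_inter - d_intra)/2 and each individual's terminal branch d_intra/2,
    so conspecific pairs diverge by d_intra and heterospecific pairs by
    d_inter in expectation.  Overlap-pair species share a single ancestor.
    """
    stem = (config.d_inter - config.d_intra) / 2.0
    tip = config.d_intra / 2.0
    root = rng.integers(0, 4, size=length, dtype=np.uint8)

    ancestors: list[np.ndarray] = []
    overlap = config.overlap_pair
    shared: np.ndarray | None = None
    for sp_idx in range(config.n_species):
        if overlap is not None and sp_idx in overlap:
            if shared is None:
                shared = evolve(root, stem, config.kappa, rng)
            ancestors.append(shared)
        else:
            ancestors.append(evolve(root, stem, config.kappa, rng))

    records: list[tuple[SpecimenRecord, str]] = []
    all_records = _specimen_records(config)
    idx = 0
    for sp_idx, count in enumerate(config.n_per_species):
        for _ in range(count):
            seq = evolve(ancestors[sp_idx], tip, config.kappa, rng)
            records.append((all_records[idx], _decode(seq)))
            idx += 1
    if config.d_outgroup is not None:
        # outgroup diverges from the root itself
        seq = evolve(root, config.d_outgroup - stem - tip if config.d_outgroup
                     > stem + tip else config.d_outgroup, config.kappa, rng)
        records.append((all_records[idx], _decode(seq)))
    return AlignedLocus(locus_name, records)


def simulate_dataset(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, AlignedLocus], dict[str, SpecimenRecord], dict]:
    """Simulate every locus of a dataset from one seeded RNG.

    Returns (loci by name, metadata by specimen_id, ground-truth dict with
    the design distances and seed).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    loci = {
        name: simulate_locus(config, length, rng, locus_name=name)
        for name, length in zip(config.locus_names, config.locus_lengths)
    }
    metadata = {rec.specimen_id: rec for rec in _specimen_records(config)}
    truth = {
        "d_intra": config.d_intra,
        "d_inter": config.d_inter,
        "kappa": config.kappa,
        "overlap_pair": (
            [config.species_names[i] for i in config.overlap_pair]
            if config.overlap_pair is not None else None
        ),
        "species_tree": "star",
        "seed": config.seed,
        "locus_lengths": dict(zip(config.locus_names, config.locus_lengths)),
    }
    return loci, metadata, truth


def simulate_pair(
    d: float,
    length: int,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Two sequences at expected K2P distance ``d`` (for calibration tests)."""
    a = rng.integers(0, 4, size=length, dtype=np.uint8)
    b = evolve(a, d, kappa, rng)
    return _decode(a), _decode(b)


def simulate_flow_sample(
    n_events: int,
    ref_mean: float,
    ratio: float,
    cv_ref: float = 0.05,
    cv_sample: float = 0.05,
    debris_fraction: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthetic one-channel fluorescence events for a two-peak run.

    Non-debris events split equally between the reference population
    (mean ``ref_mean``, sd ``cv_ref * ref_mean``) and the sample population
    (mean ``ratio * ref_mean``).  Debris events come from an exponential at
    0.2x the smaller peak mean.  Negative draws are redrawn.
    """
    if n_events < 1:
        raise UsageError("need at least one event")
    if ref_mean <= 0 or ratio <= 0:
        raise UsageError("means must be positive")
    if not 0 <= debris_fraction < 1:
        raise UsageError("debris_fraction must be in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng

    n_debris = int(round(n_events * debris_fraction))
    n_signal = n_events - n_debris
    n_ref = n_signal // 2
    n_sample = n_signal - n_ref
    sample_mean = ratio * ref_mean

    def normal(n: int, mean: float, sd: float) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        x = rng.normal(mean, sd, size=n)
        while True:
            neg = x <= 0
            if not neg.any():
                return x
            x[neg] = rng.normal(mean, sd, size=int(neg.sum()))

    parts = [
        normal(n_ref, ref_mean, cv_ref * ref_mean),
        normal(n_sample, sample_mean, cv_sample * sample_mean),
    ]
    if n_debris:
        parts.append(rng.exponential(0.2 * min(ref_mean, sample_mean), size=n_debris))
    events = np.concatenate(parts)
    rng.shuffle(events)
    return events


def write_dataset(
    loci: dict[str, AlignedLocus],
    metadata: dict[str, SpecimenRecord],
    truth: dict,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write per-locus FASTA, the metadata TSV and the ground-truth JSON."""
    from . import seqio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, locus in loci.items():
        p = outdir / f"{name}.fasta"
        seqio.write_fasta_alignment(locus, p)
        paths[name] = p
    meta_path = outdir / "metadata.tsv"
    seqio.write_metadata(metadata, meta_path)
    paths["metadata"] = meta_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    paths["truth"] = truth_path
    return paths


def write_flow_events(events: np.ndarray, path: str | Path) -> None:
    """One-column CSV of fluorescence values."""
    np.savetxt(path, events, fmt="%.6f", header="fluorescence", comments="")
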