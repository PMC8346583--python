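"""Barcode-gap statistics: intraspecific vs interspecific K2P distances.

For each species the key quantities are its maximum intraspecific distance
(MaxID) and its minimum distance to any heterospecific specimen (MinID).
A barcode gap exists when the smallest interspecific distance across the
whole dataset exceeds the largest intraspecific distance: identification by
distance is then unambiguous.  Species pairs whose minimum interspecific
distance is exactly zero are reported separately — they cannot be separated
by the locus at all, and an analyst may choose to exclude them from the
headline statistics (exclusion is always explicit, never automatic).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .exceptions import MetadataError, UsageError
from .k2p import DistanceMatrix
from .seqio import SpecimenRecord

logger = logging.getLogger("barcodegap")


@dataclass(frozen=True)
class SpeciesGapRow:
    """Per-species barcode-gap summary (one row of the report table)."""

    species: str
    n_individuals: int
    max_intra: float  # NaN when the species has a single individual
    min_inter: float
    nearest_heterospecific: str


@dataclass
class GapSummary:
    """Dataset-level barcode-gap verdict plus per-species rows."""

    rows: list[SpeciesGapRow]
    global_max_intra: float
    global_min_inter: float
    gap_exists: bool
    zero_separation_pairs: list[tuple[str, str]]
    excluded_species: list[str] = field(default_factory=list)
    n_skipped_pairs: int = 0

    def row(self, species: str) -> SpeciesGapRow:
        for r in self.rows:
            if r.species == species:
                return r
        raise KeyError(species)


def partition_distances(
    matrix: DistanceMatrix,
    metadata: dict[str, SpecimenRecord],
) -> tuple[dict[str, list[float]], dict[tuple[str, str], list[float]], int]:
    """Split defined off-diagonal distances into conspecific sets (per
    species) and heterospecific sets (per unordered species pair).

    Outgroup specimens belong to neither set.  Returns the two mappings and
    the count of undefined (NaN) pairs that were skipped.
    """
    for lab in matrix.labels:
        if lab not in metadata:
            raise MetadataError(f"matrix label {lab!r} not in metadata")
    labels = [lab for lab in matrix.labels if metadata[lab].status != "outgroup"]
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    for lab in labels:  # species in first-appearance order, deterministically
        intra.setdefault(metadata[lab].species, [])
    skipped = 0
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = matrix[a, b]
            if math.isnan(d):
                skipped += 1
                continue
            sp_a, sp_b = metadata[a].species, metadata[b].species
            if sp_a == sp_b:
                intra[sp_a].append(d)
            else:
                key = tuple(sorted((sp_a, sp_b)))
                inter.setdefault(key, []).append(d)
    if skipped:
        logger.warning("partition_distances: skipped %d undefined pair(s)", skipped)
    return intra, inter, skipped


def species_gap_table(
    matrix: DistanceMatrix,
    metadata: dict[str, SpecimenRecord],
    exclude: list[str] | tuple[str, ...] = (),
) -> GapSummary:
    """Compute per-species MaxID/MinID and the global barcode-gap verdict.

    ``exclude`` removes species from the per-species rows and the global
    statistics, mirroring the analyst decision to drop species pairs that a
    locus cannot separate; zero-separation pairs are detected BEFORE
    exclusion so the overlap is always reported.
    """
    intra, inter, skipped = partition_distances(matrix, metadata)

    zero_pairs = sorted(pair for pair, ds in inter.items() if ds and min(ds) == 0.0)

    excluded = [sp for sp in exclude if sp in intra]
    kept = [sp for sp in intra if sp not in excluded]
    if len(kept) < 2:
        raise UsageError(
            f"need >=2 species after exclusion, have {len(kept)}"
        )

    counts: dict[str, int] = {sp: 0 for sp in intra}
    for lab in matrix.labels:
        rec = metadata[lab]
        if rec.status != "outgroup":
            counts[rec.species] += 1

    rows: list[SpeciesGapRow] = []
    for sp in kept:
        max_intra = max(intra[sp]) if intra[sp] else math.nan
        best_d, best_sp = math.inf, ""
        for other in kept:
            if other == sp:
                continue
            key = tuple(sorted((sp, other)))
            ds = inter.get(key, [])
            if ds and min(ds) < best_d:
                best_d, best_sp = min(ds), other
        rows.append(SpeciesGapRow(sp, counts[sp], max_intra,
                                  best_d if best_d < math.inf else math.nan, best_sp))

    defined_max = [r.max_intra for r in rows if not math.isnan(r.max_intra)]
    global_max_intra = max(defined_max) if defined_max else math.nan
    all_inter = [d for pair, ds in inter.items()
                 if pair[0] in kept and pair[1] in kept for d in ds]
    global_min_inter = min(all_inter) if all_inter else math.nan

    if math.isnan(global_max_intra):
        # No species has two individuals: a gap means any interspecific
        # divergence at all.
        gap = (not math.isnan(global_min_inter)) and global_min_inter > 0.0
    else:
        gap = (not math.isnan(global_min_inter)) and global_min_inter > global_max_intra

    return GapSummary(rows, global_max_intra, global_min_inter, gap,
                      zero_pairs, excluded, skipped)


def _round_half_up(x: float, decimals: int) -> str:
    q = Decimal(10) ** -decimals
    return str(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_gap_table(
    summaries: dict[str, GapSummary],
    decimals: int = 2,
) -> pd.DataFrame:
    """Render per-locus/combination gap summaries as a percent table.

    One column per locus or combination, one row per species (MaxID %) plus
    a final "Min ID %" row holding the global minimum interspecific
    distance.  Distances are multiplied by 100 and rounded half-up;
    undefined entries print as an en dash.
    """
    if not summaries:
        raise UsageError("need at least one gap summary")
    species: list[str] = []
    for summary in summaries.values():
        for row in summary.rows:
            if row.species not in species:
                species.append(row.species)

    def cell(x: float) -> str:
        return "–" if math.isnan(x) else _round_half_up(100.0 * x, decimals)

    table = {}
    for name, summary in summaries.items():
        col = []
        by_sp = {r.species: r for r in summary.rows}
        for sp in species:
            col.append(cell(by_sp[sp].max_intra) if sp in by_sp else "–")
        col.append(cell(summary.global_min_inter))
        table[name] = col
    return pd.DataFrame(table, index=species + ["Min ID %"])


# Backwards-friendly alias: the table follows the classic per-locus
# MaxID/MinID report layout.
format_table2 = format_gap_table


def pair_assignments(
    matrix: DistanceMatrix,
    metadata: dict[str, SpecimenRecord],
) -> pd.DataFrame:
    """Long-format dump of every defined pair with its intra/inter class."""
    labels = [lab for lab in matrix.labels if metadata[lab].status != "outgroup"]
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = matrix[a, b]
            if math.isnan(d):
                continue
            sp_a, sp_b = metadata[a].species, metadata[b].species
            rows.append((a, b, sp_a, sp_b, "intra" if sp_a == sp_b else "inter", d))
    return pd.DataFrame(
        rows,
        columns=["specimen_a", "specimen_b", "species_a", "species_b", "class", "distance"],
    )


def write_gap_report(summaries: dict[str, GapSummary], path: str | Path,
                     decimals: int = 2) -> None:
    """Write the percent table as CSV alongside a plain-text rendering."""
    df = format_gap_table(summaries, decimals)
    path = Path(path)
    df.to_csv(path)
    with open(path.with_suffix(".txt"), "w") as fh:
        fh.write(df.to_string())
        fh.write("\n")
        for name, s in summaries.items():
            fh.write(
                f"\n{name}: gap_exists={s.gap_exists} "
                f"(MaxID={100 * s.global_max_intra:.{decimals}f}%, "
                f"MinID={100 * s.global_min_inter:.{decimals}f}%)"
            )
            if s.zero_separation_pairs:
                fh.write(f"; zero-separation pairs: {s.zero_separation_pairs}")
            if s.excluded_species:
                fh.write(f"; excluded: {s.excluded_species}")
        fh.write("\n")
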