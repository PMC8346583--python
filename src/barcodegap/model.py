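"""Model/Results front end over the barcoding and flow-cytometry pipelines.

Two fitted-model pairs, in the statsmodels idiom:

* :class:`BarcodeGapModel` holds aligned loci plus specimen metadata;
  ``fit()`` computes, per locus and per declared combination, the K2P
  distance matrix, the barcode-gap summary, and (when possible) a rooted NJ
  tree with per-species monophyly calls, returning a
  :class:`BarcodeGapResults` whose ``summary()`` prints the familiar
  MaxID/MinID percent table.

* :class:`GenomeSizeModel` holds replicate flow-cytometry event lists and a
  declared internal reference; ``fit()`` detects peaks, applies CV quality
  control and scales the reference 1C, returning
  :class:`GenomeSizeResults`.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import flowcyto, gap_analysis, k2p, njtree, seqio
from .exceptions import ConfigError, DetectionError, UsageError
from .seqio import AlignedLocus, SpecimenRecord

logger = logging.getLogger("barcodegap")


class BarcodeGapModel:
    """Multi-locus barcode-gap analysis bound to data.

    Parameters
    ----------
    loci : ordered mapping of locus name to AlignedLocus.
    metadata : specimen_id -> SpecimenRecord.
    combinations : locus-name tuples to concatenate and analyse in addition
        to each single locus; defaults to the full concatenation when more
        than one locus is given.
    outgroup : specimen_id(s) used to root NJ trees; outgroup-status
        specimens are used automatically when present.
    exclude_species : species left out of the gap table's headline
        statistics (zero-separation pairs are still reported).
    """

    def __init__(
        self,
        loci: Mapping[str, AlignedLocus],
        metadata: Mapping[str, SpecimenRecord],
        combinations: Sequence[Sequence[str]] | None = None,
        outgroup: str | Sequence[str] | None = None,
        exclude_species: Sequence[str] = (),
        min_sites: int = 100,
        deletion: Literal["pairwise", "complete"] = "pairwise",
        concat_policy: Literal["strict", "pad"] = "strict",
    ):
        self.loci = dict(loci)
        self.metadata = dict(metadata)
        if combinations is None and len(self.loci) > 1:
            combinations = [tuple(self.loci)]
        self.combinations = [tuple(c) for c in (combinations or [])]
        for combo in self.combinations:
            unknown = [name for name in combo if name not in self.loci]
            if unknown:
                raise ConfigError(f"combination {combo} references unknown loci {unknown}")
            if len(combo) < 2:
                raise ConfigError(f"combination {combo} must name >=2 loci")
        if outgroup is None:
            auto = [sid for sid, rec in self.metadata.items() if rec.status == "outgroup"]
            outgroup = auto or None
        self.outgroup = [outgroup] if isinstance(outgroup, str) else (
            list(outgroup) if outgroup else None
        )
        self.exclude_species = list(exclude_species)
        self.min_sites = min_sites
        self.deletion = deletion
        self.concat_policy = concat_policy

    @classmethod
    def from_files(
        cls,
        fasta_paths: Mapping[str, str | Path],
        metadata_path: str | Path,
        **kwargs,
    ) -> "BarcodeGapModel":
        """Build from per-locus FASTA paths and a metadata TSV."""
        metadata = seqio.read_metadata(metadata_path)
        loci = {
            name: seqio.read_fasta_alignment(path, metadata, locus_name=name)
            for name, path in fasta_paths.items()
        }
        return cls(loci, metadata, **kwargs)

    def _analysis_units(self) -> dict[str, AlignedLocus]:
        units = dict(self.loci)
        for combo in self.combinations:
            concat = seqio.concatenate_loci(
                [self.loci[name] for name in combo], policy=self.concat_policy
            )
            units[concat.locus_name] = concat
        return units

    def fit(self) -> "BarcodeGapResults":
        """Run distances, gap statistics and NJ/monophyly for every unit."""
        units = self._analysis_units()
        matrices: dict[str, k2p.DistanceMatrix] = {}
        summaries: dict[str, gap_analysis.GapSummary] = {}
        trees: dict[str, "njtree.TreeNode"] = {}
        monophyly: dict[str, dict[str, bool]] = {}
        for name, locus in units.items():
            matrix = k2p.pairwise_matrix(locus, min_sites=self.min_sites,
                                         deletion=self.deletion)
            matrices[name] = matrix
            summaries[name] = gap_analysis.species_gap_table(
                matrix, self.metadata, exclude=self.exclude_species
            )
            if matrix.is_complete and len(matrix) >= 3:
                tree = njtree.neighbor_joining(matrix)
                if self.outgroup:
                    tree = njtree.root_with_outgroup(tree, self.outgroup)
                    monophyly[name] = njtree.species_monophyly(tree, self.metadata)
                trees[name] = tree
            else:
                logger.warning(
                    "unit %s: skipping NJ tree (undefined distances or <3 taxa)", name
                )
        return BarcodeGapResults(self, matrices, summaries, trees, monophyly)


class BarcodeGapResults:
    """Fitted barcode-gap analysis: distance matrices, gap summaries,
    NJ-surrogate trees and monophyly calls, keyed by locus/combination."""

    def __init__(self, model, matrices, summaries, trees, monophyly):
        self.model = model
        self.matrices = matrices
        self.gap_summaries = summaries
        self.trees = trees
        self.monophyly = monophyly

    @property
    def table(self) -> pd.DataFrame:
        """MaxID/MinID percent table across loci and combinations."""
        return gap_analysis.format_gap_table(self.gap_summaries)

    def summary(self, decimals: int = 2) -> str:
        lines = ["Barcode gap analysis (K2P distances, NJ-surrogate trees)", ""]
        lines.append(gap_analysis.format_gap_table(self.gap_summaries, decimals).to_string())
        lines.append("")
        for name, s in self.gap_summaries.items():
            verdict = "gap" if s.gap_exists else "NO gap"
            mi = "NA" if math.isnan(s.global_max_intra) else f"{100 * s.global_max_intra:.{decimals}f}%"
            lines.append(
                f"{name}: {verdict} (max intraspecific {mi}, "
                f"min interspecific {100 * s.global_min_inter:.{decimals}f}%)"
            )
            if s.zero_separation_pairs:
                pairs = ", ".join(f"{a}/{b}" for a, b in s.zero_separation_pairs)
                lines.append(f"  zero-separation pairs: {pairs}")
            if s.excluded_species:
                lines.append(f"  excluded from table: {', '.join(s.excluded_species)}")
            if name in self.monophyly:
                non_mono = [sp for sp, ok in self.monophyly[name].items() if not ok]
                lines.append(
                    "  monophyly (NJ surrogate): "
                    + ("all species monophyletic" if not non_mono
                       else "non-monophyletic: " + ", ".join(sorted(non_mono)))
                )
        return "\n".join(lines)

    def plot_distances(self, unit: str | None = None, ax=None):
        """Histogram of intraspecific vs interspecific distances (percent)."""
        import matplotlib.pyplot as plt

        unit = unit or next(iter(self.gap_summaries))
        intra, inter, _ = gap_analysis.partition_distances(
            self.matrices[unit], self.model.metadata
        )
        intra_all = [100 * d for ds in intra.values() for d in ds]
        inter_all = [100 * d for ds in inter.values() for d in ds]
        if ax is None:
            _, ax = plt.subplots()
        bins = np.linspace(0, max(inter_all + intra_all + [0.1]) * 1.05, 40)
        ax.hist(intra_all, bins=bins, alpha=0.6, label="intraspecific")
        ax.hist(inter_all, bins=bins, alpha=0.6, label="interspecific")
        ax.set_xlabel("K2P distance (%)")
        ax.set_ylabel("pairs")
        ax.set_title(f"{unit}: barcode gap")
        ax.legend()
        return ax

    def save(self, outdir: str | Path) -> None:
        """Write matrices (CSV + PHYLIP), gap report, newick trees and
        monophyly TSVs under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, matrix in self.matrices.items():
            safe = name.replace("+", "_plus_")
            matrix.to_csv(outdir / f"distances_{safe}.csv")
            matrix.to_phylip(outdir / f"distances_{safe}.phy")
        gap_analysis.write_gap_report(self.gap_summaries, outdir / "gap_table.csv")
        for name, tree in self.trees.items():
            safe = name.replace("+", "_plus_")
            njtree.write_newick(tree, outdir / f"njtree_{safe}.nwk")
            if name in self.monophyly:
                njtree.write_monophyly_report(
                    self.monophyly[name], self.model.metadata,
                    outdir / f"monophyly_{safe}.tsv",
                )


class GenomeSizeModel:
    """Flow-cytometric genome sizing bound to replicate event lists.

    ``replicates`` maps a replicate label to a 1-D event array; the
    internal reference is declared by known 1C (pg) and by whether its peak
    is the smaller- or larger-mean of the two.
    """

    def __init__(
        self,
        replicates: Mapping[str, np.ndarray],
        reference_1C: float,
        reference_is: Literal["smaller", "larger"],
        reference_name: str = "reference",
        cv_threshold: float = 10.0,
        bins: int = 512,
        smooth_window: int = 5,
    ):
        if not replicates:
            raise UsageError("need at least one replicate event list")
        self.replicates = {k: np.asarray(v, dtype=float) for k, v in replicates.items()}
        self.reference_1C = reference_1C
        self.reference_is = reference_is
        self.reference_name = reference_name
        self.cv_threshold = cv_threshold
        self.bins = bins
        self.smooth_window = smooth_window

    @classmethod
    def from_files(
        cls,
        paths: Sequence[str | Path],
        reference_1C: float,
        reference_is: Literal["smaller", "larger"],
        **kwargs,
    ) -> "GenomeSizeModel":
        replicates = {Path(p).stem: flowcyto.read_events(p) for p in paths}
        return cls(replicates, reference_1C, reference_is, **kwargs)

    def fit(self) -> "GenomeSizeResults":
        """Detect peaks and estimate 1C per replicate; failures are kept as
        flagged rows rather than aborting the remaining replicates."""
        estimates: dict[str, flowcyto.GenomeSizeEstimate | None] = {}
        for name, events in self.replicates.items():
            try:
                estimates[name] = flowcyto.estimate_from_events(
                    events, self.reference_1C, self.reference_is,
                    cv_threshold=self.cv_threshold,
                    reference_name=self.reference_name,
                    bins=self.bins, smooth_window=self.smooth_window,
                )
            except DetectionError as exc:
                logger.warning("replicate %s: peak detection failed (%s)", name, exc)
                estimates[name] = None
        return GenomeSizeResults(self, estimates)


class GenomeSizeResults:
    """Per-replicate genome-size estimates plus the aggregate 1C mean."""

    def __init__(self, model: GenomeSizeModel, estimates):
        self.model = model
        self.estimates = estimates

    @property
    def table(self) -> pd.DataFrame:
        return flowcyto.replicate_report(self.estimates)

    @property
    def successful(self) -> list[flowcyto.GenomeSizeEstimate]:
        return [e for e in self.estimates.values() if e is not None]

    @property
    def mean_1C(self) -> float:
        """Mean 1C (pg) over successful replicates."""
        return flowcyto.aggregate_1c(self.successful)

    @property
    def qc_pass(self) -> bool:
        ok = self.successful
        return bool(ok) and all(e.qc_pass for e in ok)

    def summary(self) -> str:
        lines = [
            f"Genome size vs {self.model.reference_name} "
            f"(1C = {self.model.reference_1C} pg, "
            f"reference peak = {self.model.reference_is}-mean)",
            "",
            self.table.to_string(index=False),
            "",
        ]
        if self.successful:
            lines.append(
                f"aggregate 1C = {self.mean_1C:.4f} pg over "
                f"{len(self.successful)} replicate(s); "
                f"QC (CV < {self.model.cv_threshold}%): "
                + ("pass" if self.qc_pass else "FAIL")
            )
        else:
            lines.append("no successful replicate estimates")
        return "\n".join(lines)

    def plot(self, replicate: str | None = None, ax=None):
        """Fluorescence histogram with detected peak means marked."""
        import matplotlib.pyplot as plt

        replicate = replicate or next(iter(self.model.replicates))
        events = self.model.replicates[replicate]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(events, bins=self.model.bins)
        if self.estimates.get(replicate) is not None:
            peaks = flowcyto.detect_peaks(events, n_peaks=2, bins=self.model.bins,
                                          smooth_window=self.model.smooth_window)
            for p in peaks:
                ax.axvline(p.mean, color="red", linestyle="--")
        ax.set_xlabel("fluorescence (channel)")
        ax.set_ylabel("events")
        ax.set_title(f"{replicate}")
        return ax
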