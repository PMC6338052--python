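"""Model/Results interface over the APA pipeline.

:class:`APA` is built from a segmentation and two replicate groups; ``fit()``
returns an :class:`APAResults` carrying per-gene roar values, all-pairings
Fisher p-values, expression filters, calls and a ``summary()`` table.
:class:`TimeCourseAPA` fits one comparison per non-baseline time point and
intersects the calls into a consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotation import ApaSegmentation
from .classify import ApaCall, ConsensusResult, Thresholds, classify_gene, consensus
from .quant import RegionCounts
from .stats import GeneApaStat, pooled_gene_stat, stats_to_frame


class APA:
    """Per-gene APA shortening/lengthening model for one comparison.

    Parameters
    ----------
    segmentations
        gene_id -> :class:`ApaSegmentation`; defines PRE/POST geometry.
    baseline, contrast
        Replicate :class:`RegionCounts` of the two conditions (baseline =
        proliferating/earlier, contrast = differentiated/later; roar > 1 then
        reads as shortening in the contrast condition).
    name
        Comparison label, e.g. ``"T0vsT3"``.
    """

    def __init__(
        self,
        segmentations: Mapping[str, ApaSegmentation],
        baseline: Sequence[RegionCounts],
        contrast: Sequence[RegionCounts],
        name: Optional[str] = None,
    ) -> None:
        if not segmentations:
            raise ValueError("empty segmentation")
        if not baseline or not contrast:
            raise ValueError("need at least one replicate per condition")
        conds_b = {rc.condition for rc in baseline}
        conds_c = {rc.condition for rc in contrast}
        self.segmentations = dict(segmentations)
        self.baseline = list(baseline)
        self.contrast = list(contrast)
        self.name = name or (
            f"{next(iter(conds_b))}vs{next(iter(conds_c))}"
            if len(conds_b) == 1 and len(conds_c) == 1
            else "baseline_vs_contrast"
        )
        common = set(segmentations)
        for rc in (*baseline, *contrast):
            common &= set(rc.counts)
        self.gene_ids = sorted(common)
        if not self.gene_ids:
            raise ValueError("no genes shared by segmentation and all samples")

    @classmethod
    def from_tables(
        cls,
        segmentation_bed,
        baseline_paths: Sequence,
        contrast_paths: Sequence,
        name: Optional[str] = None,
    ) -> "APA":
        """Build from a segmentation BED and counts-table files."""
        from .annotation import read_segmentation_bed
        from .quant import read_counts_table

        return cls(
            read_segmentation_bed(segmentation_bed),
            [read_counts_table(p) for p in baseline_paths],
            [read_counts_table(p) for p in contrast_paths],
            name=name,
        )

    def fit(
        self,
        alpha: float = 0.05,
        fpkm_min: float = 1.0,
        roar_boundary: float = 1.0,
    ) -> "APAResults":
        thresholds = Thresholds(
            roar_boundary=roar_boundary, alpha=alpha, fpkm_min=fpkm_min
        )
        stats: dict[str, GeneApaStat] = {}
        calls: dict[str, ApaCall] = {}
        for gene_id in self.gene_ids:
            stat = pooled_gene_stat(
                self.baseline, self.contrast, self.segmentations[gene_id], gene_id
            )
            stats[gene_id] = stat
            calls[gene_id] = classify_gene(stat, self.name, thresholds)
        return APAResults(self, thresholds, stats, calls)


@dataclass
class APAResults:
    """Fitted per-gene APA statistics and calls for one comparison."""

    model: APA
    thresholds: Thresholds
    stats: dict[str, GeneApaStat]
    calls: dict[str, ApaCall]

    @property
    def frame(self):
        """Per-gene results as a pandas DataFrame (includes the call column)."""
        frame = stats_to_frame(self.stats)
        frame["call"] = [self.calls[g].call for g in frame["gene_id"]]
        frame["reasons"] = [",".join(self.calls[g].reasons) for g in frame["gene_id"]]
        return frame

    def genes_called(self, call: str) -> frozenset[str]:
        return frozenset(g for g, c in self.calls.items() if c.call == call)

    def summary(self) -> str:
        n = len(self.calls)
        lines = [
            f"APA comparison {self.model.name}",
            f"  genes analyzed:     {n}",
            f"  baseline replicates: {len(self.model.baseline)}"
            f"   contrast replicates: {len(self.model.contrast)}",
            f"  thresholds: roar boundary {self.thresholds.roar_boundary},"
            f" alpha {self.thresholds.alpha}, FPKM > {self.thresholds.fpkm_min}",
        ]
        for call in ("SHORTENED", "LENGTHENED", "UNCHANGED", "NOT_TESTABLE"):
            k = len(self.genes_called(call))
            lines.append(f"  {call:<13} {k:>6}  ({100.0 * k / n:.1f}%)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")

    def plot_roar(self, ax=None):
        """Volcano-style plot: log2 roar vs -log10 of the worst pairing p."""
        import math

        import matplotlib.pyplot as plt
        import numpy as np

        if ax is None:
            _, ax = plt.subplots()
        colors = {"SHORTENED": "tab:red", "LENGTHENED": "tab:blue"}
        for gene_id, stat in self.stats.items():
            if stat.roar is None or stat.roar <= 0 or not stat.pairwise_pvalues:
                continue
            worst = max(stat.pairwise_pvalues)
            if math.isnan(worst):
                continue
            ax.scatter(
                np.log2(stat.roar),
                -np.log10(max(worst, 1e-300)),
                s=8,
                color=colors.get(self.calls[gene_id].call, "0.7"),
            )
        ax.axvline(0, color="k", lw=0.5)
        ax.axhline(-np.log10(self.thresholds.alpha), color="k", lw=0.5, ls="--")
        ax.set_xlabel("log2 roar (contrast/baseline m/M)")
        ax.set_ylabel("-log10 max pairing p")
        ax.set_title(self.model.name)
        return ax


class TimeCourseAPA:
    """Baseline-vs-each-later-time-point comparisons plus their consensus."""

    def __init__(
        self,
        segmentations: Mapping[str, ApaSegmentation],
        samples: Sequence[RegionCounts],
        baseline: str = "T0",
    ) -> None:
        conditions = []
        for rc in samples:
            if rc.condition not in conditions:
                conditions.append(rc.condition)
        if baseline not in conditions:
            raise ValueError(f"baseline condition {baseline!r} not among samples")
        if len(conditions) < 2:
            raise ValueError("need at least two conditions")
        self.baseline = baseline
        self.conditions = conditions
        self.samples = list(samples)
        self.models = {}
        base_reps = [rc for rc in samples if rc.condition == baseline]
        for cond in conditions:
            if cond == baseline:
                continue
            reps = [rc for rc in samples if rc.condition == cond]
            name = f"{baseline}vs{cond}"
            self.models[name] = APA(segmentations, base_reps, reps, name=name)

    def fit(
        self,
        alpha: float = 0.05,
        fpkm_min: float = 1.0,
        roar_boundary: float = 1.0,
    ) -> "TimeCourseResults":
        results = {
            name: model.fit(alpha=alpha, fpkm_min=fpkm_min, roar_boundary=roar_boundary)
            for name, model in self.models.items()
        }
        calls = {name: res.calls for name, res in results.items()}
        cons = consensus(calls, sorted(results))
        return TimeCourseResults(self, results, cons)


@dataclass
class TimeCourseResults:
    model: TimeCourseAPA
    comparisons: dict[str, APAResults]
    consensus: ConsensusResult

    def summary(self) -> str:
        lines = [
            f"APA time course: baseline {self.model.baseline}, "
            f"{len(self.comparisons)} comparisons"
        ]
        for name in sorted(self.comparisons):
            res = self.comparisons[name]
            lines.append(
                f"  {name}: shortened {len(res.genes_called('SHORTENED'))}, "
                f"lengthened {len(res.genes_called('LENGTHENED'))}"
            )
        lines.append(
            f"  always shortened:  {len(self.consensus.always_shortened)}"
        )
        lines.append(
            f"  always lengthened: {len(self.consensus.always_lengthened)}"
        )
        return "\n".join(lines)
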