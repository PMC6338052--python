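"""qPCR quantification of long vs common 3'UTR isoform abundance.

The wet-lab design amplifies each transcript twice: one primer pair specific
to the long-3'UTR form and one pair in the common region (long + short
forms), alongside a reference gene (e.g. GAPDH).  With amplification
efficiency E the relative long-form abundance index of one replicate is

    index = E^-((ct_long - ct_ref) - (ct_common - ct_ref)) = E^-(ct_long - ct_common)

(the reference cancels within a replicate but is required to be measured).
Replicates are combined by geometric mean, equivalent to averaging Ct values.
The between-condition ratio index_contrast / index_baseline exceeds 1 when
the long form gains relative abundance in the contrast condition
(lengthening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


@dataclass(frozen=True)
class QpcrMeasurement:
    """Replicate Ct triples (long, common, reference) for one gene+condition."""

    gene_id: str
    condition: str
    replicates: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("need at least one replicate")
        for trip in self.replicates:
            if len(trip) != 3:
                raise ValueError("each replicate needs (ct_long, ct_common, ct_reference)")
            for ct in trip:
                if ct is None or not math.isfinite(ct) or ct <= 0:
                    raise ValueError(f"invalid Ct value {ct!r}")


def long_fraction_index(m: QpcrMeasurement, efficiency: float = 2.0) -> float:
    """Relative abundance of the long form vs total, geometric-mean combined."""
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    logs = [
        -(ct_long - ct_common) * math.log(efficiency)
        for ct_long, ct_common, _ct_ref in m.replicates
    ]
    return math.exp(sum(logs) / len(logs))


def condition_ratio(
    baseline: QpcrMeasurement, contrast: QpcrMeasurement, efficiency: float = 2.0
) -> float:
    """Long-form index ratio contrast/baseline; > 1 means relative lengthening."""
    if baseline.gene_id != contrast.gene_id:
        raise ValueError(
            f"gene mismatch: {baseline.gene_id} vs {contrast.gene_id}"
        )
    idx_b = long_fraction_index(baseline, efficiency)
    if idx_b == 0:
        raise ValueError("zero baseline index")
    return long_fraction_index(contrast, efficiency) / idx_b


def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a Ct TSV: gene_id, condition, replicate, ct_long, ct_common, ct_reference."""
    grouped: dict[tuple[str, str], list[tuple[int, tuple[float, float, float]]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "gene_id", "condition", "replicate", "ct_long", "ct_common", "ct_reference",
        ]
        if header != expected:
            raise ValueError(f"bad Ct table header {header!r}")
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 6 or any(v == "" for v in f):
                raise ValueError(f"{path}:{ln}: missing Ct field")
            key = (f[0], f[1])
            grouped.setdefault(key, []).append(
                (int(f[2]), (float(f[3]), float(f[4]), float(f[5])))
            )
    out = []
    for (gene_id, condition), reps in sorted(grouped.items()):
        reps.sort(key=lambda r: r[0])
        out.append(
            QpcrMeasurement(
                gene_id=gene_id,
                condition=condition,
                replicates=tuple(trip for _, trip in reps),
            )
        )
    return out
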