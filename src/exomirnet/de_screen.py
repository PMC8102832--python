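"""Exosomal miRNA differential screening.

Counts are library-size normalized to reads per million (RPM), Z-scored per
miRNA over all samples jointly (so a single heat-map scale covers every
group), and differential calls between two groups are made on the difference
of group-mean Z values. Because the exosome libraries may be pooled (one
pseudo-replicate per group), no p-value is attached at this layer; the
reported fold change is a pseudocounted RPM ratio.

A treatment "reversal" (rescue) is a miRNA that moves one way in disease
vs control and the opposite way under treatment vs disease. The consistency
screen then intersects exosomal calls with tissue miRNA differential tables
under the |logFC| >= 1, p <= 0.05 criteria, keeping only miRNAs with the same
direction in both compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import DifferentialRecord, ExpressionMatrix, harmonize_mirna

__all__ = [
    "ReversalCall",
    "ConsistentDEmiR",
    "compute_rpm",
    "zscore",
    "call_differential",
    "classify_reversal",
    "consistency_screen",
]

REVERSAL_PATTERNS = ("rescued_down", "rescued_up", "not_reversed")


@dataclass(frozen=True)
class ReversalCall:
    """Treatment-reversal pattern of one miRNA across the two comparisons.

    rescued_down: down in disease vs control, up under treatment vs disease.
    rescued_up: the mirror pattern.
    """

    mirna_id: str
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in REVERSAL_PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass(frozen=True)
class ConsistentDEmiR:
    """A miRNA differential in the same direction in exosomes and tissue."""

    mirna_id: str
    direction: str
    exosome: DifferentialRecord
    tissue: DifferentialRecord

    def __post_init__(self) -> None:
        if not (self.exosome.direction == self.tissue.direction == self.direction):
            raise ValueError(f"{self.mirna_id}: directions disagree")


def compute_rpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads-per-million normalization: count / column sum * 1e6."""
    if m.unit != "raw_count":
        raise ValueError(f"compute_rpm expects raw counts, got {m.unit!r}")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"zero-library sample(s): {', '.join(zero.index)}")
    rpm = m.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=rpm, unit="rpm", group_of=dict(m.group_of))


def zscore(m: ExpressionMatrix, axis: str = "per_feature") -> ExpressionMatrix:
    """Per-feature Z transform: (x - mean) / sd, sample sd (ddof=1).

    Constant features become all-zero rows and are flagged rather than
    producing NaNs.
    """
    if axis != "per_feature":
        raise ValueError(f"unsupported axis {axis!r}")
    if m.values.shape[1] < 2:
        raise ValueError("zscore needs at least 2 samples per feature")
    arr = m.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (arr - mean) / sd_safe
    z[constant, :] = 0.0
    flags = {m.feature_ids[i]: "constant" for i in np.flatnonzero(constant)}
    return ExpressionMatrix(
        values=pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        unit="zscore",
        group_of=dict(m.group_of),
        flags=flags,
    )


def call_differential(
    z: ExpressionMatrix,
    rpm: ExpressionMatrix,
    group_a: str,
    group_b: str,
    z_cut: float = 1.0,
    dataset_id: str = "exosome",
    pseudocount: float = 1.0,
) -> list[DifferentialRecord]:
    """Call miRNAs differential between ``group_b`` and ``group_a``.

    A miRNA is differential when |mean Z(b) - mean Z(a)| >= ``z_cut``; the
    direction is the sign of that delta. The reported log2 fold change is
    log2((mean RPM_b + c) / (mean RPM_a + c)) with pseudocount c, so calls
    remain usable under a pooled single-replicate design.
    """
    if z.unit != "zscore" or rpm.unit != "rpm":
        raise ValueError("call_differential expects a zscore and an rpm matrix")
    a = z.samples_in_group(group_a)
    b = z.samples_in_group(group_b)
    if not a or not b:
        raise ValueError(f"empty group: {group_a if not a else group_b!r}")
    dz = z.values[b].mean(axis=1) - z.values[a].mean(axis=1)
    mean_a = rpm.values[a].mean(axis=1)
    mean_b = rpm.values[b].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    records: list[DifferentialRecord] = []
    for mirna in z.feature_ids:
        delta = float(dz[mirna])
        if abs(delta) < z_cut or z.flags.get(mirna) == "constant":
            continue
        fc = float(lfc[mirna])
        # direction is carried by the sign of log2fc and must follow the Z
        # delta; force agreement when the pseudocounted ratio straddles zero
        if delta > 0 and fc <= 0:
            fc = 1e-9
        elif delta < 0 and fc >= 0:
            fc = -1e-9
        records.append(
            DifferentialRecord(
                feature_id=mirna,
                layer="exosome_mirna",
                dataset_id=dataset_id,
                log2fc=fc,
            )
        )
    return records


def classify_reversal(
    de_disease_vs_control: Sequence[DifferentialRecord],
    de_treated_vs_disease: Sequence[DifferentialRecord],
) -> list[ReversalCall]:
    """Partition miRNAs seen in either comparison into reversal patterns."""
    d1 = {r.feature_id: r.direction for r in de_disease_vs_control}
    d2 = {r.feature_id: r.direction for r in de_treated_vs_disease}
    calls = []
    for mirna in sorted(set(d1) | set(d2)):
        pair = (d1.get(mirna), d2.get(mirna))
        if pair == ("down", "up"):
            pattern = "rescued_down"
        elif pair == ("up", "down"):
            pattern = "rescued_up"
        else:
            pattern = "not_reversed"
        calls.append(ReversalCall(mirna_id=mirna, pattern=pattern))
    return calls


def consistency_screen(
    exo_de: Iterable[DifferentialRecord],
    tissue_de: Iterable[DifferentialRecord],
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
) -> list[ConsistentDEmiR]:
    """Keep miRNAs differential in exosomes AND tissue, same direction.

    Tissue records must satisfy |log2fc| >= ``lfc_cut`` and p <= ``p_cut``.
    Ids are matched after stripping species prefixes (mouse exosome data vs
    human tissue arrays name the same mature miRNA differently).
    """
    tissue_by_key: dict[str, DifferentialRecord] = {}
    for rec in tissue_de:
        tissue_by_key[harmonize_mirna(rec.feature_id)] = rec
    out: list[ConsistentDEmiR] = []
    for exo in sorted(exo_de, key=lambda r: r.feature_id):
        tis = tissue_by_key.get(harmonize_mirna(exo.feature_id))
        if tis is None or tis.p is None:
            continue
        if abs(tis.log2fc) < lfc_cut or tis.p > p_cut:
            continue
        if tis.direction != exo.direction:
            continue
        out.append(
            ConsistentDEmiR(
                mirna_id=exo.feature_id,
                direction=exo.direction,
                exosome=exo,
                tissue=tis,
            )
        )
    return out
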