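"""Seed-based miRNA target prediction and multi-omics candidate-DEG screening.

Target sites are canonical seed matches in the 3'-UTR: with the miRNA seed
defined as nucleotides 2-8, a UTR site is the reverse complement of the seed
(7mer-m8), optionally followed by an adenosine opposite miRNA position 1
(8mer), or the reverse complement of nucleotides 2-7 with (7mer-A1) or
without (6mer) that A. Site types rank 8mer > 7mer-m8 > 7mer-A1 > 6mer.

A gene's targeting score combines its sites as a noisy-OR over per-type
weights; pairs at or above a retention threshold (default 0.7) are kept.
Externally produced prediction tables (e.g. from a target-prediction server)
can be substituted for the built-in scanner.

The candidate-DEG screen then applies the opposite-trend rule: a predicted
target is a candidate only if its differential direction is opposite to its
regulator miRNA's, consistently across the mRNA datasets in which it is
measured, with the proteome layer contributing direction evidence without a
fold-change floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .de_screen import ConsistentDEmiR
from .io_formats import DifferentialRecord, harmonize_gene, normalize_rna

__all__ = [
    "SeedMatch",
    "TargetPrediction",
    "CandidateDEGSet",
    "SITE_WEIGHTS",
    "seed_of",
    "find_seed_sites",
    "score_target",
    "predict_targets",
    "opposite_trend_filter",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

#: per-site weights of the noisy-OR composite score
SITE_WEIGHTS = {"8mer": 0.9, "7mer-m8": 0.75, "7mer-A1": 0.6, "6mer": 0.3}

_SITE_LEN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedMatch:
    """One seed-match site on a UTR (0-based half-open coordinates)."""

    mirna_id: str
    gene_id: str
    site_type: str
    utr_start: int
    utr_end: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.utr_end - self.utr_start != _SITE_LEN[self.site_type]:
            raise ValueError(
                f"{self.site_type} span must be {_SITE_LEN[self.site_type]} nt"
            )


@dataclass(frozen=True)
class TargetPrediction:
    """A retained miRNA -> gene link with its seed-site evidence."""

    mirna_id: str
    gene_id: str
    score: float
    sites: tuple[SeedMatch, ...] = ()
    source: str = "seed_scan"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.source not in ("seed_scan", "external"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class CandidateDEGSet:
    """Candidate target genes split by direction, with layer provenance."""

    genes_up: set[str] = field(default_factory=set)
    genes_down: set[str] = field(default_factory=set)
    n_transcriptome: int = 0
    n_proteome: int = 0
    n_both: int = 0

    @property
    def all_genes(self) -> set[str]:
        return self.genes_up | self.genes_down

    def check_identity(self) -> None:
        """Inclusion-exclusion over the two layers must account for every candidate."""
        if self.n_transcriptome + self.n_proteome - self.n_both != len(self.all_genes):
            raise AssertionError("layer provenance counts violate inclusion-exclusion")


def seed_of(mirna_seq: str) -> str:
    """Seed = miRNA nucleotides 2-8 (1-based inclusive), a 7-mer."""
    seq = normalize_rna(mirna_seq, context="miRNA")
    if len(seq) < 8:
        raise ValueError(f"miRNA shorter than 8 nt: {seq!r}")
    return seq[1:8]


def find_seed_sites(
    mirna_seq: str,
    utr_seq: str,
    mirna_id: str = "mirna",
    gene_id: str = "gene",
) -> list[SeedMatch]:
    """Scan a 3'-UTR 5'->3' for canonical seed-match sites.

    Each UTR occurrence is reported once under its highest-ranked type:
    an occurrence of the 7-nt seed match followed by A is an 8mer, without
    the A a 7mer-m8; a 6-nt match (seed nt 2-7) not embedded in a 7-nt match
    is a 7mer-A1 when followed by A, else a 6mer. Overlapping hits of the
    same type are all reported.
    """
    seed = seed_of(mirna_seq)
    utr = normalize_rna(utr_seq, context="UTR")
    r7 = _revcomp(seed)        # matches seed nt 2-8
    r6 = _revcomp(seed[:6])    # matches seed nt 2-7; r7 == comp(nt8) + r6
    sites: list[SeedMatch] = []
    r7_starts: set[int] = set()
    i = utr.find(r7)
    while i != -1:
        r7_starts.add(i)
        if i + 7 < len(utr) and utr[i + 7] == "A":
            sites.append(SeedMatch(mirna_id, gene_id, "8mer", i, i + 8))
        else:
            sites.append(SeedMatch(mirna_id, gene_id, "7mer-m8", i, i + 7))
        i = utr.find(r7, i + 1)
    j = utr.find(r6)
    while j != -1:
        # skip 6-mers that are the tail of a 7-nt match already reported
        if (j - 1) not in r7_starts:
            if j + 6 < len(utr) and utr[j + 6] == "A":
                sites.append(SeedMatch(mirna_id, gene_id, "7mer-A1", j, j + 7))
            else:
                sites.append(SeedMatch(mirna_id, gene_id, "6mer", j, j + 6))
        j = utr.find(r6, j + 1)
    sites.sort(key=lambda s: (s.utr_start, SITE_TYPES.index(s.site_type)))
    return sites


def score_target(sites: Sequence[SeedMatch]) -> float:
    """Noisy-OR composite: 1 - prod(1 - w_i) over per-site weights."""
    score = 1.0
    for s in sites:
        score *= 1.0 - SITE_WEIGHTS[s.site_type]
    return 1.0 - score


def predict_targets(
    demirs: Sequence[ConsistentDEmiR | str],
    mirna_seqs: Mapping[str, str],
    utr_seqs: Mapping[str, str],
    threshold: float = 0.7,
    external: Sequence[TargetPrediction] | None = None,
) -> list[TargetPrediction]:
    """All (miRNA, gene) pairs with composite score >= ``threshold``.

    ``demirs`` may be ConsistentDEmiR records or bare miRNA ids. When an
    ``external`` prediction table is supplied it replaces the seed scan
    (rows below the threshold or for non-screened miRNAs are dropped).
    """
    ids = [d if isinstance(d, str) else d.mirna_id for d in demirs]
    if external is not None:
        keep = set(ids)
        return sorted(
            (p for p in external if p.mirna_id in keep and p.score >= threshold),
            key=lambda p: (p.mirna_id, p.gene_id),
        )
    missing = [m for m in ids if m not in mirna_seqs]
    if missing:
        raise ValueError(f"no sequence for miRNA(s): {', '.join(sorted(missing))}")
    out: list[TargetPrediction] = []
    for mirna in sorted(ids):
        for gene in sorted(utr_seqs):
            sites = find_seed_sites(mirna_seqs[mirna], utr_seqs[gene], mirna, gene)
            score = score_target(sites)
            if score >= threshold:
                out.append(
                    TargetPrediction(
                        mirna_id=mirna, gene_id=gene, score=score, sites=tuple(sites)
                    )
                )
    return out


def _passes(rec: DifferentialRecord, direction: str, lfc_cut: float, p_cut: float) -> bool:
    if rec.direction != direction:
        return False
    if abs(rec.log2fc) < lfc_cut:
        return False
    return rec.p is None or rec.p <= p_cut


def opposite_trend_filter(
    demirs: Sequence[ConsistentDEmiR],
    predictions: Sequence[TargetPrediction],
    mrna_tables: Mapping[str, Sequence[DifferentialRecord]],
    protein_table: Sequence[DifferentialRecord] | None = None,
    lfc_cut: float = 2.0,
    p_cut: float = 0.05,
    min_support: int | str = "all",
) -> CandidateDEGSet:
    """Screen predicted targets for the opposite-trend rule across omics layers.

    A gene enters ``genes_up`` iff it is a predicted target of at least one
    down-regulated DEmiR and is called up — passing |log2fc| >= ``lfc_cut``
    and p <= ``p_cut`` — in at least ``min_support`` of the mRNA datasets in
    which it is measured (``"all"``: every dataset where it appears), or is
    up in the protein layer (same p rule, no fold-change floor). Mirror rule
    for ``genes_down``. Genes with conflicting directions between layers are
    dropped. Provenance counts record how many candidates carry
    transcriptome evidence, proteome evidence, or both.
    """
    if not predictions:
        warnings.warn("empty prediction list: no candidate DEGs", stacklevel=2)
        return CandidateDEGSet()
    dir_of_mirna = {d.mirna_id: d.direction for d in demirs}
    # genes targeted by at least one DEmiR of each direction
    targets_of_down: set[str] = set()
    targets_of_up: set[str] = set()
    for p in predictions:
        g = harmonize_gene(p.gene_id)
        mdir = dir_of_mirna.get(p.mirna_id)
        if mdir == "down":
            targets_of_down.add(g)
        elif mdir == "up":
            targets_of_up.add(g)

    # transcriptome consensus per gene
    t_dir: dict[str, str] = {}
    measured: dict[str, int] = {}
    support: dict[str, dict[str, int]] = {}
    for records in mrna_tables.values():
        seen: set[str] = set()
        for rec in records:
            g = harmonize_gene(rec.feature_id)
            if g in seen:
                continue
            seen.add(g)
            measured[g] = measured.get(g, 0) + 1
            sup = support.setdefault(g, {"up": 0, "down": 0})
            for direction in ("up", "down"):
                if _passes(rec, direction, lfc_cut, p_cut):
                    sup[direction] += 1
    for g, sup in support.items():
        need = measured[g] if min_support == "all" else int(min_support)
        calls = [d for d in ("up", "down") if sup[d] >= need]
        if len(calls) == 1:
            t_dir[g] = calls[0]

    # proteome direction (no fold-change floor; p applied when present)
    p_dir: dict[str, str] = {}
    for rec in protein_table or ():
        g = harmonize_gene(rec.feature_id)
        if rec.p is not None and rec.p > p_cut:
            continue
        if rec.log2fc == 0.0:
            continue
        p_dir[g] = rec.direction

    result = CandidateDEGSet()
    for g in sorted(set(t_dir) | set(p_dir)):
        dirs = {d for d in (t_dir.get(g), p_dir.get(g)) if d is not None}
        if len(dirs) != 1:
            warnings.warn(f"{g}: transcriptome/proteome directions conflict; dropped",
                          stacklevel=2)
            continue
        (direction,) = dirs
        opposing = targets_of_down if direction == "up" else targets_of_up
        if g not in opposing:
            continue
        (result.genes_up if direction == "up" else result.genes_down).add(g)
        in_t = g in t_dir
        in_p = g in p_dir
        result.n_transcriptome += in_t
        result.n_proteome += in_p
        result.n_both += in_t and in_p
    result.check_identity()
    return result
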