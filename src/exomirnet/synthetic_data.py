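"""Self-consistent synthetic study generator with recorded ground truth.

The generator emulates the statistical structure of a three-group exosomal
small-RNA study (control, disease, treated) integrated with tissue-level
differential tables: negative-binomial miRNA count matrices with a
treatment-reversed subset, a tissue miRNA table sign-consistent with a
chosen subset of the exosomal calls, several mRNA datasets sharing a
sign-consistent core of planted target genes, a small overlapping proteome
table, 3'-UTR sequences carrying planted seed sites for the planted
miRNA -> gene pairs, a PPI edge list with one dense module around the
headline axis gene, and paired expression matrices in which planted pairs
are negatively correlated.

Every planted feature is given an effect size comfortably above the default
screening thresholds, so a pipeline run at defaults recovers the recorded
ground truth; the one designated (miRNA, gene) axis carries an 8mer site and
the strongest planted anti-correlation, mirroring a rescued miRNA repressing
an inflammatory chemokine.

``make_worked_fixture`` builds two small deterministic fixtures encoding
printed component sets (layer sizes 40/193 transcripts and 3/5 proteins with
a 3-gene overlap; and the 9-gene pathway / 12-gene module hub union).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .de_screen import ConsistentDEmiR
from .io_formats import (
    DifferentialRecord,
    ExpressionMatrix,
    GeneSetCollection,
    write_differential_table,
    write_edge_list,
    write_fasta,
    write_gmt,
    write_matrix,
)
from .target_screen import TargetPrediction, seed_of

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_study",
    "planted_module_graph",
    "make_worked_fixture",
]

GROUPS = ("NC", "ACLF", "MSC")

#: the headline axis miRNA sequence (a canonical mature miRNA; seed AAAGUGC,
#: whose 8mer UTR site is GCACUUUA)
AXIS_MIRNA_SEQ = "UAAAGUGCUUAUAGUGCAGGUAG"

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated study: 56 treatment-rescued down-regulated
    and 60 rescued up-regulated exosomal miRNAs, of which 6 down and 30 up
    are sign-consistent with the tissue layer; planted effect sizes sit above
    the screening thresholds (|log2FC| >= 1 miRNA, >= 2 mRNA) and planted
    pairs target an anti-correlation around -0.8 at the 0.6 screening cutoff.
    """

    n_mirnas: int = 300
    n_genes: int = 400
    n_mrna_datasets: int = 4
    samples_per_group: int = 3
    library_size: int = 1_000_000
    nb_size: float = 50.0          # negative-binomial shape (1/dispersion)
    effect_size: float = 3.0       # |log2FC| of planted exosomal miRNAs
    mrna_lfc: float = 2.5          # |log2FC| of planted core DEGs (>= 2)
    noise_sd: float = 1.0          # expression noise, correlation matrices
    corr_strength: float = 0.8     # |r| of planted pairs (screen cut: 0.6)
    n_corr_samples: int = 30
    n_rescued_down: int = 56
    n_rescued_up: int = 60
    n_consistent_down: int = 6
    n_consistent_up: int = 30
    module_size: int = 12
    pathway_size: int = 9
    pathway_module_overlap: int = 6
    n_extra_planted: int = 10
    n_protein_only: int = 2
    n_both_layers: int = 5
    module_edge_p: float = 0.9
    background_edge_p: float = 0.01
    utr_length: int = 120
    mirna_length: int = 22
    noise_genes_per_dataset: int = 40
    n_decoy_sets: int = 19
    seed: int = 0

    def validate(self) -> None:
        if self.n_rescued_down + self.n_rescued_up > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        if self.n_consistent_down > self.n_rescued_down:
            raise ValueError("consistent-down set exceeds rescued-down set")
        if self.n_consistent_up > self.n_rescued_up:
            raise ValueError("consistent-up set exceeds rescued-up set")
        n_planted_genes = (
            self.module_size
            + (self.pathway_size - self.pathway_module_overlap)
            + self.n_extra_planted
        )
        if n_planted_genes * 2 > self.n_genes:
            raise ValueError("too many planted genes for the gene universe")
        if self.pathway_module_overlap > min(self.pathway_size, self.module_size):
            raise ValueError("pathway/module overlap larger than the sets")
        if self.n_protein_only > self.n_extra_planted:
            raise ValueError("protein-only genes must come from the extra planted pool")
        if self.effect_size < 1.0 or self.mrna_lfc < 2.0:
            raise ValueError("planted effects must clear the screening thresholds")
        if not (0.6 <= self.corr_strength < 1.0):
            raise ValueError("planted correlation must clear the 0.6 screen")


@dataclass
class GroundTruth:
    """What was planted, so every downstream stage has a recoverable answer."""

    reversed_down_mirnas: set[str]
    reversed_up_mirnas: set[str]
    consistent_demirs: dict[str, str]          # miRNA -> direction
    planted_pairs: set[tuple[str, str]]        # (miRNA, gene)
    planted_module: set[str]
    pathway_genes: set[str]
    planted_axis: tuple[str, str]
    gene_direction: dict[str, str]
    regulator_of: dict[str, str]               # gene -> its planted miRNA

    def __post_init__(self) -> None:
        if self.planted_axis not in self.planted_pairs:
            raise ValueError("planted_axis must be one of the planted pairs")


@dataclass
class StudyBundle:
    """Every artifact of one synthetic study, in memory."""

    exo_counts: ExpressionMatrix
    tissue_table: list[DifferentialRecord]
    mrna_tables: dict[str, list[DifferentialRecord]]
    protein_table: list[DifferentialRecord]
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    ppi_edges: list[tuple[str, str, float]]
    gene_sets: GeneSetCollection
    mirna_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    library_sizes: dict[str, float] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(self.exo_counts, out / "exosome_counts.tsv")
        with open(out / "groups.tsv", "w", encoding="utf-8") as fh:
            fh.write("sample_id\tgroup\n")
            for s in self.exo_counts.sample_ids:
                fh.write(f"{s}\t{self.exo_counts.group_of[s]}\n")
        write_differential_table(self.tissue_table, out / "tissue_mirna.tsv")
        for ds, recs in self.mrna_tables.items():
            write_differential_table(recs, out / f"{ds}.tsv")
        write_differential_table(self.protein_table, out / "protein.tsv")
        write_fasta(self.mirna_seqs, out / "mirna.fa")
        write_fasta(self.utr_seqs, out / "utr.fa")
        write_edge_list(self.ppi_edges, out / "ppi_edges.tsv")
        write_gmt(self.gene_sets, out / "gene_sets.gmt")
        write_matrix(self.mirna_expr, out / "mirna_expression.tsv")
        write_matrix(self.gene_expr, out / "gene_expression.tsv")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _has_strong_site(utr: str, seeds: list[str]) -> bool:
    """True if the UTR contains a 7mer-m8 (hence also any 8mer) of any seed."""
    return any(_revcomp(seed) in utr for seed in seeds)


def generate_study(config: SynthConfig) -> tuple[StudyBundle, GroundTruth]:
    """Generate one fully self-consistent study and its ground truth.

    Deterministic given the config (including its seed): calling twice with
    the same config yields identical bundles.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(8)]
    (rng_counts, rng_tissue, rng_mrna, rng_seq,
     rng_ppi, rng_sets, rng_corr, rng_misc) = rngs

    mirnas = [f"mir-{i + 1:04d}" for i in range(config.n_mirnas)]
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]

    # --- planted miRNA structure -----------------------------------------
    rescued_down = mirnas[: config.n_rescued_down]
    rescued_up = mirnas[config.n_rescued_down : config.n_rescued_down + config.n_rescued_up]
    consistent: dict[str, str] = {}
    for m in rescued_down[: config.n_consistent_down]:
        consistent[m] = "down"       # down in disease, in exosomes and tissue
    for m in rescued_up[: config.n_consistent_up]:
        consistent[m] = "up"
    axis_mirna = rescued_down[0]

    # --- planted gene structure ------------------------------------------
    n_pathway_only = config.pathway_size - config.pathway_module_overlap
    n_planted = config.module_size + n_pathway_only + config.n_extra_planted
    planted_genes = genes[:n_planted]
    module_genes = set(planted_genes[: config.module_size])
    pathway_genes = set(
        planted_genes[: config.pathway_module_overlap]
        + planted_genes[config.module_size : config.module_size + n_pathway_only]
    )
    extra_genes = planted_genes[config.module_size + n_pathway_only :]
    protein_only = set(extra_genes[: config.n_protein_only])
    axis_gene = planted_genes[0]     # in the module (and the pathway overlap)

    # regulators: up genes are repressed by down miRNAs and vice versa; the
    # axis gene is up (repressor lost in disease) under the axis miRNA
    down_regulators = [m for m, d in consistent.items() if d == "down"]
    up_regulators = [m for m, d in consistent.items() if d == "up"]
    gene_direction: dict[str, str] = {}
    regulator_of: dict[str, str] = {}
    d_i = u_i = 0
    for k, g in enumerate(planted_genes):
        if g == axis_gene or k % 3 == 0:   # roughly one third up-regulated
            gene_direction[g] = "up"
            regulator_of[g] = axis_mirna if g == axis_gene else down_regulators[
                d_i % len(down_regulators)
            ]
            d_i += 1
        else:
            gene_direction[g] = "down"
            regulator_of[g] = up_regulators[u_i % len(up_regulators)]
            u_i += 1
    planted_pairs = {(regulator_of[g], g) for g in planted_genes}

    truth = GroundTruth(
        reversed_down_mirnas=set(rescued_down),
        reversed_up_mirnas=set(rescued_up),
        consistent_demirs=consistent,
        planted_pairs=planted_pairs,
        planted_module=module_genes,
        pathway_genes=pathway_genes,
        planted_axis=(axis_mirna, axis_gene),
        gene_direction=gene_direction,
        regulator_of=regulator_of,
    )

    # --- exosomal count matrix (negative binomial, library-size scaled) ---
    base_rel = rng_counts.lognormal(mean=0.0, sigma=1.5, size=config.n_mirnas)
    fold = 2.0 ** config.effect_size
    # planted baselines: bounded away from count noise, and balanced so the
    # library share lost by the down set in disease matches the share gained
    # by the up set (no compositional shift onto the null miRNAs)
    n_down, n_up = config.n_rescued_down, config.n_rescued_up
    planted_base = np.clip(
        rng_counts.lognormal(mean=0.0, sigma=0.5, size=n_down + n_up), 0.3, 2.0
    )
    base_rel[:n_down] = planted_base[:n_down] * fold * (n_up / n_down)
    base_rel[n_down : n_down + n_up] = planted_base[n_down:]
    base_rel /= base_rel.sum()
    samples = [f"{g}_{r + 1}" for g in GROUPS for r in range(config.samples_per_group)]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}
    mat = np.zeros((config.n_mirnas, len(samples)))
    for j, s in enumerate(samples):
        grp = group_of[s]
        rel = base_rel.copy()
        if grp == "ACLF":
            rel[: config.n_rescued_down] /= fold
            rel[config.n_rescued_down : config.n_rescued_down + config.n_rescued_up] *= fold
        # NC and MSC share the baseline: the treated group is restored
        mean = rel / rel.sum() * config.library_size
        p = config.nb_size / (config.nb_size + mean)
        mat[:, j] = rng_counts.negative_binomial(config.nb_size, p)
    exo_counts = ExpressionMatrix(
        values=pd.DataFrame(mat, index=mirnas, columns=samples),
        unit="raw_count",
        group_of=group_of,
    )

    # --- tissue miRNA differential table ----------------------------------
    tissue: list[DifferentialRecord] = []
    for m, d in sorted(consistent.items()):
        lfc = float(rng_tissue.uniform(1.5, 3.0))
        tissue.append(
            DifferentialRecord(
                feature_id=f"hsa-{m}", layer="tissue_mirna", dataset_id="tissue",
                log2fc=lfc if d == "up" else -lfc,
                p=float(rng_tissue.uniform(1e-6, 0.01)),
            )
        )
    # decoys: planted exosomal miRNAs whose tissue trend is opposite
    n_decoy = min(10, config.n_rescued_down - config.n_consistent_down)
    for m in rescued_down[config.n_consistent_down : config.n_consistent_down + n_decoy]:
        tissue.append(
            DifferentialRecord(
                feature_id=f"hsa-{m}", layer="tissue_mirna", dataset_id="tissue",
                log2fc=float(rng_tissue.uniform(1.5, 3.0)),   # up while exosome is down
                p=float(rng_tissue.uniform(1e-6, 0.01)),
            )
        )
    # tissue-only noise miRNAs, absent from the exosome matrix
    for i in range(30):
        lfc = float(rng_tissue.normal(0.0, 1.5))
        tissue.append(
            DifferentialRecord(
                feature_id=f"hsa-tis-mir-{i + 1:03d}", layer="tissue_mirna",
                dataset_id="tissue", log2fc=lfc if lfc != 0 else 0.1,
                p=float(rng_tissue.uniform(0.0, 1.0)),
            )
        )

    # --- mRNA datasets with a sign-consistent planted core ----------------
    core_mrna = [g for g in planted_genes if g not in protein_only]
    noise_pool = genes[n_planted:]
    mrna_tables: dict[str, list[DifferentialRecord]] = {}
    for d in range(config.n_mrna_datasets):
        ds = f"mrna_ds{d + 1}"
        recs: list[DifferentialRecord] = []
        for g in core_mrna:
            lfc = float(rng_mrna.uniform(config.mrna_lfc, config.mrna_lfc + 1.5))
            recs.append(
                DifferentialRecord(
                    feature_id=g, layer="mrna", dataset_id=ds,
                    log2fc=lfc if gene_direction[g] == "up" else -lfc,
                    p=float(rng_mrna.uniform(1e-8, 0.009)),
                )
            )
        noise = rng_mrna.choice(noise_pool, size=config.noise_genes_per_dataset, replace=False)
        for g in noise:
            lfc = float(rng_mrna.normal(0.0, 1.5))
            recs.append(
                DifferentialRecord(
                    feature_id=str(g), layer="mrna", dataset_id=ds,
                    log2fc=lfc if lfc != 0 else 0.1,
                    p=float(rng_mrna.uniform(0.0, 1.0)),
                )
            )
        mrna_tables[ds] = recs

    # --- proteome table overlapping the transcriptome core ----------------
    both_layer = [g for g in core_mrna if g != axis_gene][: config.n_both_layers - 1]
    both_layer = [axis_gene] + both_layer
    protein: list[DifferentialRecord] = []
    for g in list(protein_only) + both_layer:
        lfc = float(rng_misc.uniform(0.8, 2.0))
        protein.append(
            DifferentialRecord(
                feature_id=g, layer="protein", dataset_id="proteome",
                log2fc=lfc if gene_direction[g] == "up" else -lfc,
                p=float(rng_misc.uniform(1e-5, 0.01)),
            )
        )
    for i in range(3):   # protein-only noise ids, not predicted targets
        lfc = float(rng_misc.normal(0.0, 1.0))
        protein.append(
            DifferentialRecord(
                feature_id=f"PROT{i + 1:02d}", layer="protein", dataset_id="proteome",
                log2fc=lfc if lfc != 0 else 0.1, p=None,
            )
        )

    # --- sequences: miRNAs with unique seeds, UTRs with planted sites -----
    mirna_seqs: dict[str, str] = {}
    seen_seeds: set[str] = set()
    for m in mirnas:
        if m == axis_mirna:
            seq = AXIS_MIRNA_SEQ
        else:
            seq = _random_rna(rng_seq, config.mirna_length)
            while seq[1:8] in seen_seeds or seq[1:8] == AXIS_MIRNA_SEQ[1:8]:
                seq = _random_rna(rng_seq, config.mirna_length)
        seen_seeds.add(seq[1:8])
        mirna_seqs[m] = seq
    planted_seeds = [seed_of(mirna_seqs[m]) for m in sorted(consistent)]

    utr_seqs: dict[str, str] = {}
    for g in genes:
        utr = _random_rna(rng_seq, config.utr_length)
        while _has_strong_site(utr, planted_seeds):
            utr = _random_rna(rng_seq, config.utr_length)
        utr_seqs[g] = utr
    for g in planted_genes:   # insert one 8mer site of the gene's regulator
        site = _revcomp(seed_of(mirna_seqs[regulator_of[g]])) + "A"
        pos = int(rng_seq.integers(0, config.utr_length - len(site)))
        utr = utr_seqs[g]
        utr_seqs[g] = utr[:pos] + site + utr[pos + len(site):]

    # --- PPI edge list with one dense module -------------------------------
    ppi_nodes = planted_genes + noise_pool[:25]
    ppi_edges = planted_module_graph(
        nodes=ppi_nodes,
        module=sorted(module_genes),
        p_in=config.module_edge_p,
        p_out=config.background_edge_p,
        rng=rng_ppi,
    )

    # --- gene-set collection -----------------------------------------------
    sets: dict[str, tuple[str, list[str]]] = {
        "PATH0001": ("cytokine-cytokine receptor interaction", sorted(pathway_genes))
    }
    for i in range(config.n_decoy_sets):
        size = int(rng_sets.integers(8, 31))
        members = sorted(rng_sets.choice(genes, size=size, replace=False))
        sets[f"PATH{i + 2:04d}"] = (f"decoy pathway {i + 1}", members)
    gene_sets = GeneSetCollection.from_sets(sets, universe=genes)

    # --- paired expression matrices for the correlation screen -------------
    corr_samples = [f"S{i + 1:03d}" for i in range(config.n_corr_samples)]
    mir_rows = sorted(consistent)
    x = rng_corr.normal(0.0, 1.0, size=(len(mir_rows), config.n_corr_samples))
    mirna_expr = ExpressionMatrix(
        values=pd.DataFrame(x, index=mir_rows, columns=corr_samples),
        unit="arbitrary_expression",
    )
    gene_rows = planted_genes + noise_pool[:20]
    rho = config.corr_strength
    y = np.zeros((len(gene_rows), config.n_corr_samples))
    mi = {m: i for i, m in enumerate(mir_rows)}
    for i, g in enumerate(gene_rows):
        eps = rng_corr.normal(0.0, config.noise_sd, size=config.n_corr_samples)
        if g in regulator_of:
            # plant the empirical sample correlation: mix the standardized
            # miRNA vector with noise orthogonalized against it, so the
            # realized Pearson r equals the drawn target exactly
            r_t = -(rho + rng_corr.uniform(-0.05, 0.05))
            xv = x[mi[regulator_of[g]]]
            xc = xv - xv.mean()
            xs = xc / np.linalg.norm(xc)
            ec = eps - eps.mean()
            ec -= (xs @ ec) * xs
            es = ec / np.linalg.norm(ec)
            y[i] = r_t * xs + np.sqrt(1.0 - r_t**2) * es
        else:
            y[i] = eps
    gene_expr = ExpressionMatrix(
        values=pd.DataFrame(y, index=gene_rows, columns=corr_samples),
        unit="arbitrary_expression",
    )

    bundle = StudyBundle(
        exo_counts=exo_counts,
        tissue_table=tissue,
        mrna_tables=mrna_tables,
        protein_table=protein,
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        ppi_edges=ppi_edges,
        gene_sets=gene_sets,
        mirna_expr=mirna_expr,
        gene_expr=gene_expr,
        library_sizes={s: float(mat[:, j].sum()) for j, s in enumerate(samples)},
    )
    return bundle, truth


def planted_module_graph(
    nodes: list[str],
    module: list[str],
    p_in: float = 0.9,
    p_out: float = 0.05,
    rng: np.random.Generator | int = 0,
) -> list[tuple[str, str, float]]:
    """Random graph with one dense planted module over ``module`` nodes.

    Within-module pairs get an edge with probability ``p_in``, every other
    pair with probability ``p_out``; weights are uniform, higher inside the
    module.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mod = set(module)
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            inside = a in mod and b in mod
            p = p_in if inside else p_out
            if rng.random() < p:
                w = float(rng.uniform(0.6, 1.0) if inside else rng.uniform(0.15, 0.6))
                edges.append((a, b, w))
    return edges


# ---------------------------------------------------------------------------
# worked fixtures encoding printed component sets
# ---------------------------------------------------------------------------

#: genes enriched in the cytokine-cytokine receptor interaction pathway
#: (5 down-regulated, 4 up-regulated)
PATHWAY_GENES_DOWN = ("GHR", "LEPR", "CXCL2", "IL1RN", "IL1RAP")
PATHWAY_GENES_UP = ("CXCL6", "CXCL8", "CXCL14", "TNFRSF21")

#: the 12 interacting proteins of the core PPI module
MODULE_GENES = (
    "CXCL8", "CXCL2", "CXCL6", "CXCL14", "GPR37", "FPR3", "SSTR1",
    "ADCY1", "GUCY1A2", "PDE11A", "IL1RN", "IL1RAP",
)


def make_worked_fixture(name: str) -> dict:
    """Small deterministic fixtures for worked-example arithmetic.

    ``fig3_counts``: differential tables and predictions sized so the
    opposite-trend integration yields 40 up- and 193 down-regulated
    transcripts (233 transcriptome candidates), 3 up- and 5 down-regulated
    proteins with a 3-gene layer overlap, i.e. 238 candidates in total.

    ``hub_union``: the 9-gene enriched-pathway list, the 12-gene core-module
    list (union: 15 hub genes), dense module edges, a gene-set collection
    whose first set holds the 9 pathway genes, and external predictions
    wiring 21 miRNAs to the hubs.

    Gene names follow the emulated study's printed lists; all other ids are
    synthetic placeholders.
    """
    if name == "fig3_counts":
        return _fig3_counts_fixture()
    if name == "hub_union":
        return _hub_union_fixture()
    raise ValueError(f"unknown fixture {name!r}")


def _mk_demir(mirna: str, direction: str) -> ConsistentDEmiR:
    lfc = 2.0 if direction == "up" else -2.0
    exo = DifferentialRecord(mirna, "exosome_mirna", "exosome", lfc)
    tis = DifferentialRecord(mirna, "tissue_mirna", "tissue", lfc, p=0.001)
    return ConsistentDEmiR(mirna_id=mirna, direction=direction, exosome=exo, tissue=tis)


def _fig3_genes() -> tuple[list[str], list[str]]:
    """233 transcriptome candidate genes: 40 up, 193 down."""
    up = list(PATHWAY_GENES_UP) + [f"WFGU{i + 1:03d}" for i in range(36)]
    down = (
        list(PATHWAY_GENES_DOWN)
        + [g for g in MODULE_GENES if g not in PATHWAY_GENES_UP + PATHWAY_GENES_DOWN]
        + [f"WFGD{i + 1:03d}" for i in range(182)]
    )
    assert len(up) == 40 and len(down) == 193
    return up, down


def _fig3_counts_fixture() -> dict:
    up_genes, down_genes = _fig3_genes()
    demirs = [_mk_demir(f"wf-mir-d{i + 1}", "down") for i in range(6)] + [
        _mk_demir(f"wf-mir-u{i + 1}", "up") for i in range(30)
    ]
    down_mirnas = [d.mirna_id for d in demirs if d.direction == "down"]
    up_mirnas = [d.mirna_id for d in demirs if d.direction == "up"]

    # layer overlap: 1 up + 2 down genes measured in both layers; plus
    # protein-only candidates (2 up, 3 down) to reach 3 up / 5 down proteins
    both_up, both_down = ["CXCL8"], ["GHR", "LEPR"]
    prot_only_up = ["WFPU001", "WFPU002"]
    prot_only_down = ["WFPD001", "WFPD002", "WFPD003"]

    predictions = []
    for k, g in enumerate(up_genes + prot_only_up):
        predictions.append(
            TargetPrediction(down_mirnas[k % 6], g, score=0.9, source="external")
        )
    for k, g in enumerate(down_genes + prot_only_down):
        predictions.append(
            TargetPrediction(up_mirnas[k % 30], g, score=0.9, source="external")
        )

    mrna_tables = {}
    for d in range(4):
        ds = f"wf_ds{d + 1}"
        recs = [
            DifferentialRecord(g, "mrna", ds, 2.5, p=0.001) for g in up_genes
        ] + [
            DifferentialRecord(g, "mrna", ds, -2.5, p=0.001) for g in down_genes
        ]
        mrna_tables[ds] = recs
    protein_table = [
        DifferentialRecord(g, "protein", "wf_prot", 1.2, p=0.01)
        for g in both_up + prot_only_up
    ] + [
        DifferentialRecord(g, "protein", "wf_prot", -1.2, p=0.01)
        for g in both_down + prot_only_down
    ]
    return {
        "demirs": demirs,
        "predictions": predictions,
        "mrna_tables": mrna_tables,
        "protein_table": protein_table,
        "genes_up": up_genes + prot_only_up,
        "genes_down": down_genes + prot_only_down,
    }


def _hub_union_fixture() -> dict:
    pathway = list(PATHWAY_GENES_DOWN) + list(PATHWAY_GENES_UP)
    module = list(MODULE_GENES)
    rng = np.random.default_rng(20210423)
    module_edges = planted_module_graph(
        nodes=sorted(module), module=sorted(module), p_in=1.0, p_out=0.0, rng=rng
    )
    up_all, down_all = _fig3_genes()
    query = up_all + down_all + ["WFPU001", "WFPU002", "WFPD001", "WFPD002", "WFPD003"]
    background = [f"WFBG{i + 1:03d}" for i in range(762)]
    universe = query + background
    sets: dict[str, tuple[str, list[str]]] = {
        "hsa04060": ("cytokine-cytokine receptor interaction", pathway)
    }
    for i in range(9):
        members = sorted(rng.choice(universe, size=25, replace=False))
        sets[f"decoy{i + 1:02d}"] = (f"decoy set {i + 1}", members)
    collection = GeneSetCollection.from_sets(sets, universe=universe)

    hubs = sorted(set(pathway) | set(module))
    mirnas = [f"wf-mir-d{i + 1}" for i in range(6)] + [f"wf-mir-u{i + 1}" for i in range(15)]
    predictions = [
        TargetPrediction(mirnas[k % 21], g, score=0.9, source="external")
        for k, g in enumerate(hubs)
    ] + [
        TargetPrediction(mirnas[k], hubs[k % len(hubs)], score=0.9, source="external")
        for k in range(len(mirnas))
    ]
    return {
        "pathway_genes": pathway,
        "module_genes": module,
        "module_edges": module_edges,
        "gene_sets": collection,
        "query": query,
        "predictions": predictions,
        "mirnas": mirnas,
    }
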