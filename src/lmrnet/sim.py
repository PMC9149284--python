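"""Synthetic dataset generator with planted regulatory ground truth.

The generator emits a self-contained toy dataset — genome, GFF3 annotation,
promoter/transcript/miRNA sequences, negative-binomial count matrices over
a 3-condition x 3-replicate design, and the planted truth — exhibiting the
statistical structure the downstream analysis assumes:

* TF targets carry the TF's binding element in their promoter and co-vary
  with the TF across conditions; decoy promoters are rejection-sampled to
  exclude every instantiated motif, so motif presence <=> planted
  regulation.
* miRNA targets contain a perfect complementary site on their transcript
  and anti-vary with the miRNA.
* cis-lncRNA targets sit within the 10-kb window of their lncRNA (and only
  theirs); trans-lncRNA targets are positionally remote but anti-correlated.
* every remaining feature is a flat decoy, and lncRNA loci realize all four
  positional classes (lincRNA / intronic / antisense / sense).

Condition-trajectory geometry
-----------------------------
Centered log2 trajectories over 3 conditions live in a 2-D plane, so only a
handful of mutually low-correlated directions exist.  Directions are
therefore laid out per mechanism so that the correlation thresholds
downstream separate planted from unplanted pairs: trans pairs occupy
26-degree-spaced directions (pairwise trajectory correlation <= cos 26deg);
TF pairs, miRNA targets and cis pairs are confined to directions at least
~16-26 degrees away from every trans direction, with per-mechanism signal
amplitudes (hence signal fractions R^2) chosen so no unplanted pair can
reach the trans threshold |r| = 0.9.  TF pair precision does not rest on
this geometry at all: each TF receives its own concrete motif, so motif
gating alone separates TF pairs.  The layout constants below encode this
design; docs/methods.md derives it.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    FeatureModel,
    GenomeAnnotation,
    reverse_complement,
    write_counts,
    write_fasta,
    write_gff3,
    write_roles,
    write_sample_sheet,
)
from .lncrna import longest_orf_aa
from .tf import IUPAC, extract_promoter

# --- chromosome layout (bp) -------------------------------------------------
GENE_LEN = 2000
EXONS_REL = ((0, 600), (950, 1500), (1700, 2000))  # 1450 nt spliced
GENE_PITCH = 20_000  # start-to-start; keeps cis windows unambiguous
LNC_LEN = 500
FAR_OFFSET = 30_000  # gap between the gene block and the remote lncRNA block
FAR_PITCH = 21_000  # > 2x the 10-kb cis window
CIS_GAP_RANGE = (2_100, 6_000)  # lncRNA-to-target gap, always within 10 kb

# --- trajectory geometry (degrees on the centered-trajectory circle, log2
# amplitudes).  See the module docstring and docs/methods.md. ---------------
# Whether an unplanted pair can cross the trans threshold |r| = 0.9 is
# governed by the angle between the two condition-trajectory directions and
# by how far the *realized* directions wobble around the designed ones
# (roughly noise_sd / (sqrt(n_replicates) * amplitude) radians).  With
# three conditions the centered trajectories live on a circle, so the
# direction budget is hard: the ten trans axes take 32-degree steps over a
# 288-degree arc, and every other mechanism shares the single direction at
# 324 degrees, 36 degrees from the nearest trans axis.  Amplitudes are
# large (strong responders, 16-70 fold) so realized directions wobble by
# only a few degrees; Monte-Carlo of the negative-binomial model puts every
# unplanted channel's P(|r| >= 0.9) below ~1%.  cis lncRNAs carry no
# expression trajectory at all: cis targeting is positional in this method,
# and a DE cis-lncRNA would necessarily anti-align with some trans axis
# (its antipode falls 16 degrees from one), so the generator leaves cis
# detection to the coordinates and the target gene's differential call.
TRANS_SPACING_DEG = 32.0
CLUSTER_DIR_DEG = 324.0  # TF pairs, miRNA targets, cis target genes
MIRNA_SRC_DIR_DEG = CLUSTER_DIR_DEG - 180.0  # miRNA own trajectories
AMPLITUDE = {  # log2 units of the condition trajectory, per mechanism
    "lnc_trans": 5.0,
    "tf_binding": 4.5,
    "mirna_cleavage_src": 3.0,
    "mirna_cleavage": 4.0,
    "lnc_cis": 4.0,
}

TruthEdge = namedtuple("TruthEdge", "source_id target_id mechanism")
MotifPlacement = namedtuple("MotifPlacement", "gene_id offset strand")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    """Raised when the requested configuration cannot be realized."""


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the simulated study conditions: a 3-condition (N0/N6/N18)
    x 3-replicate design, 30/20/10/10 planted TF / miRNA / cis / trans edges
    and 100 flat decoy features split across roles.
    """

    n_genes: int = 130
    n_tfs: int = 30
    n_lncrnas: int = 40
    n_mirnas: int = 40
    n_conditions: int = 3
    n_replicates: int = 3
    chrom_length: int | None = None  # None: computed from the layout
    planted_tf_edges: int = 30
    planted_mirna_edges: int = 20
    planted_lnc_cis_edges: int = 10
    planted_lnc_trans_edges: int = 10
    target_correlation: float = 0.95
    nb_dispersion: float = 0.05
    baseline_mean_log_range: tuple[float, float] = (6.0, 10.0)  # log2 counts
    #: baseline range for flat (unregulated) features.  The stable bulk is
    #: drawn higher so it carries most of the library mass, emulating the
    #: housekeeping transcriptome that keeps per-library totals comparable
    #: across conditions in real data (FPKM/TPM totals would otherwise be
    #: driven by the responsive minority).
    background_mean_log_range: tuple[float, float] = (12.5, 14.5)
    motif_consensus: str = "TGACGTNNNN"
    promoter_length: int = 2000
    plant_motifs: bool = True
    mirna_length: int = 21
    seed: int = 0

    def conditions(self) -> list[str]:
        if self.n_conditions == 3:
            return ["N0", "N6", "N18"]
        return [f"C{i + 1}" for i in range(self.n_conditions)]

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_tfs": self.n_tfs,
            "n_lncrnas": self.n_lncrnas,
            "n_mirnas": self.n_mirnas,
            "planted_tf_edges": self.planted_tf_edges,
            "planted_mirna_edges": self.planted_mirna_edges,
            "planted_lnc_cis_edges": self.planted_lnc_cis_edges,
            "planted_lnc_trans_edges": self.planted_lnc_trans_edges,
        }
        for k, v in counts.items():
            if v < 0:
                raise SimulationError(f"{k} must be >= 0, got {v}")
        if self.n_conditions < 2 or self.n_replicates < 2:
            raise SimulationError("need >= 2 conditions and >= 2 replicates")
        if not 0 <= self.target_correlation <= 1:
            raise SimulationError("target_correlation must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be positive")
        for name in ("baseline_mean_log_range", "background_mean_log_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise SimulationError(f"{name} must be (lo, hi)")
        bad = set(self.motif_consensus.upper()) - set(IUPAC)
        if bad:
            raise SimulationError(f"motif_consensus: invalid IUPAC {sorted(bad)}")
        if len(self.motif_consensus) >= self.promoter_length:
            raise SimulationError("motif must be shorter than the promoter")
        if not 18 <= self.mirna_length <= 30:
            raise SimulationError("mirna_length must lie in [18, 30]")
        n_targets = (
            self.planted_tf_edges
            + self.planted_mirna_edges
            + self.planted_lnc_cis_edges
            + self.planted_lnc_trans_edges
        )
        n_hosts = 3 if self.n_lncrnas >= 4 else 0
        if n_targets + n_hosts > self.n_genes:
            raise SimulationError(
                f"need {n_targets} distinct target genes plus {n_hosts} host "
                f"genes but n_genes={self.n_genes}"
            )
        planted_lnc = self.planted_lnc_cis_edges + self.planted_lnc_trans_edges
        if planted_lnc > self.n_lncrnas - n_hosts:
            raise SimulationError(
                f"need {planted_lnc} lincRNA-class lncRNAs but only "
                f"{self.n_lncrnas - n_hosts} are available after reserving "
                f"positional-class exemplars"
            )
        if self.planted_mirna_edges and self.n_mirnas == 0:
            raise SimulationError("planted miRNA edges but n_mirnas == 0")
        if self.planted_tf_edges and self.n_tfs == 0:
            raise SimulationError("planted TF edges but n_tfs == 0")


@dataclass
class GroundTruth:
    edges: list[TruthEdge]
    motif_placements: list[MotifPlacement]
    expected_de_features: list[str]

    def edge_keys(self) -> set[tuple[str, str, str]]:
        return {(e.source_id, e.target_id, e.mechanism) for e in self.edges}


@dataclass
class _Plan:
    """Deterministic id bookkeeping derived from the config alone."""

    gene_ids: list[str]
    tf_ids: list[str]
    lnc_ids: list[str]
    mirna_ids: list[str]
    tf_edges: list[TruthEdge]
    mirna_edges: list[TruthEdge]
    cis_edges: list[TruthEdge]
    trans_edges: list[TruthEdge]
    exemplars: dict[str, str]  # lnc_id -> class (intronic/antisense/sense)
    hosts: dict[str, str]  # lnc_id -> host gene id
    far_lnc_ids: list[str]  # trans + decoy lincRNAs, in placement order

    @property
    def edges(self) -> list[TruthEdge]:
        return self.tf_edges + self.mirna_edges + self.cis_edges + self.trans_edges


def _plan(cfg: SimulationConfig) -> _Plan:
    gene_ids = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    tf_ids = [f"tf{i:03d}" for i in range(cfg.n_tfs)]
    lnc_ids = [f"lnc{i:03d}" for i in range(cfg.n_lncrnas)]
    mirna_ids = [f"mir{i:03d}" for i in range(cfg.n_mirnas)]

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = gene_ids[cursor : cursor + n]
        cursor += n
        return out

    tf_targets = take(cfg.planted_tf_edges)
    mi_targets = take(cfg.planted_mirna_edges)
    cis_targets_ = take(cfg.planted_lnc_cis_edges)
    trans_targets = take(cfg.planted_lnc_trans_edges)

    tf_edges = [
        TruthEdge(tf_ids[i % cfg.n_tfs], g, "tf_binding")
        for i, g in enumerate(tf_targets)
    ]
    mirna_edges = [
        TruthEdge(mirna_ids[i % cfg.n_mirnas], g, "mirna_cleavage")
        for i, g in enumerate(mi_targets)
    ]
    n_cis = cfg.planted_lnc_cis_edges
    n_trans = cfg.planted_lnc_trans_edges
    cis_lncs = lnc_ids[:n_cis]
    trans_lncs = lnc_ids[n_cis : n_cis + n_trans]
    cis_edges = [
        TruthEdge(l, g, "lnc_cis") for l, g in zip(cis_lncs, cis_targets_)
    ]
    trans_edges = [
        TruthEdge(l, g, "lnc_trans") for l, g in zip(trans_lncs, trans_targets)
    ]

    exemplars: dict[str, str] = {}
    hosts: dict[str, str] = {}
    if cfg.n_lncrnas >= 4:
        ex_ids = lnc_ids[n_cis + n_trans : n_cis + n_trans + 3]
        host_genes = gene_ids[cursor : cursor + 3]
        for lid, cls, host in zip(ex_ids, ("intronic", "antisense", "sense"), host_genes):
            exemplars[lid] = cls
            hosts[lid] = host

    far_lnc_ids = trans_lncs + lnc_ids[n_cis + n_trans + len(exemplars) :]
    return _Plan(
        gene_ids=gene_ids,
        tf_ids=tf_ids,
        lnc_ids=lnc_ids,
        mirna_ids=mirna_ids,
        tf_edges=tf_edges,
        mirna_edges=mirna_edges,
        cis_edges=cis_edges,
        trans_edges=trans_edges,
        exemplars=exemplars,
        hosts=hosts,
        far_lnc_ids=far_lnc_ids,
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _required_length(cfg: SimulationConfig, plan: _Plan) -> int:
    n_slots = cfg.n_genes + cfg.n_tfs
    far_base = cfg.promoter_length + 1000 + n_slots * GENE_PITCH + FAR_OFFSET
    return far_base + len(plan.far_lnc_ids) * FAR_PITCH + 1000


def generate_annotation(cfg: SimulationConfig) -> GenomeAnnotation:
    """Deterministic gene/TF/lncRNA placement on one chromosome.

    Genes are non-overlapping three-exon models on a wide pitch; lncRNA loci
    realize all four positional classes whenever >= 4 lncRNAs are requested;
    cis-planted lncRNAs sit 2.1-6 kb from their (sole) neighboring gene.
    Raises :class:`SimulationError` when ``chrom_length`` cannot hold the
    layout.
    """
    cfg.validate()
    plan = _plan(cfg)
    rng = np.random.default_rng([cfg.seed, 0])

    required = _required_length(cfg, plan)
    if cfg.chrom_length is not None and cfg.chrom_length < required:
        raise SimulationError(
            f"chrom_length={cfg.chrom_length} too small: placing "
            f"{cfg.n_genes + cfg.n_tfs} non-overlapping genes and "
            f"{len(plan.far_lnc_ids)} remote lncRNA loci needs >= {required} bp"
        )

    gene_order = plan.gene_ids + plan.tf_ids
    strands = rng.choice(np.array(["+", "-"]), size=len(gene_order))
    lnc_strands = rng.choice(np.array(["+", "-"]), size=cfg.n_lncrnas)
    cis_gaps = rng.integers(
        CIS_GAP_RANGE[0], CIS_GAP_RANGE[1] + 1, size=len(plan.cis_edges)
    )

    features: list[FeatureModel] = []
    gene_span: dict[str, tuple[int, int, str]] = {}
    base0 = cfg.promoter_length + 1000
    for i, gid in enumerate(gene_order):
        start = base0 + i * GENE_PITCH
        role = "TF" if gid.startswith("tf") else "mRNA"
        strand = str(strands[i])
        exons = [(start + s, start + e) for s, e in EXONS_REL]
        features.append(
            FeatureModel(
                id=gid,
                type="gene",
                chrom="chr1",
                strand=strand,
                start=start,
                end=start + GENE_LEN,
                role=role,
            )
        )
        features.append(
            FeatureModel(
                id=f"{gid}.t1",
                type="transcript",
                chrom="chr1",
                strand=strand,
                start=start,
                end=start + GENE_LEN,
                role=role,
                exons=exons,
                parent_id=gid,
            )
        )
        gene_span[gid] = (start, start + GENE_LEN, strand)

    lnc_strand_of = {lid: str(s) for lid, s in zip(plan.lnc_ids, lnc_strands)}

    def add_lnc(lid: str, start: int, strand: str, biotype: str, length: int = LNC_LEN) -> None:
        features.append(
            FeatureModel(
                id=lid,
                type="transcript",
                chrom="chr1",
                strand=strand,
                start=start,
                end=start + length,
                role="lncRNA",
                exons=[(start, start + length)],
                biotype=biotype,
            )
        )

    for (edge, gap) in zip(plan.cis_edges, cis_gaps):
        g_start, g_end, _ = gene_span[edge.target_id]
        add_lnc(edge.source_id, g_end + int(gap), lnc_strand_of[edge.source_id], "lincRNA")

    for lid, cls in plan.exemplars.items():
        h_start, h_end, h_strand = gene_span[plan.hosts[lid]]
        if cls == "intronic":
            # intron 1 spans [600, 950) relative to the gene; a 300-nt locus
            # fits fully inside (and still passes the >= 200 nt filter)
            add_lnc(lid, h_start + 625, h_strand, cls, length=300)
        elif cls == "antisense":  # overlaps exon 1 on the opposite strand
            add_lnc(lid, h_start + 200, "+" if h_strand == "-" else "-", cls)
        else:  # sense: overlaps exon 1 on the same strand
            add_lnc(lid, h_start + 100, h_strand, cls)

    far_base = base0 + len(gene_order) * GENE_PITCH + FAR_OFFSET
    for j, lid in enumerate(plan.far_lnc_ids):
        add_lnc(lid, far_base + j * FAR_PITCH, lnc_strand_of[lid], "lincRNA")

    return GenomeAnnotation(features)


# ---------------------------------------------------------------------------
# Motifs and promoters
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _contains_any_motif(seq: str, motifs: list[str]) -> bool:
    for m in motifs:
        if m in seq or reverse_complement(m) in seq:
            return True
    return False


def instantiate_motifs(
    tf_ids: list[str], consensus: str, rng: np.random.Generator
) -> dict[str, str]:
    """One concrete motif per TF, drawn from the degenerate consensus.

    Distinct realizations are enforced while the consensus has enough
    degeneracy; otherwise realizations repeat (with a much weaker
    precision guarantee downstream, which the caller accepts knowingly).
    """
    consensus = consensus.upper()
    n_possible = math.prod(len(IUPAC[c]) for c in consensus)
    out: dict[str, str] = {}
    seen: set[str] = set()
    for tf in tf_ids:
        for _ in range(500):
            motif = "".join(
                IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in consensus
            )
            if motif not in seen or len(seen) >= n_possible:
                break
        seen.add(motif)
        out[tf] = motif
    return out


def plant_motifs(
    annotation: GenomeAnnotation,
    motif_consensus: str,
    tf_edges: list[TruthEdge],
    seed: int,
    promoter_length: int = 2000,
    plant: bool = True,
) -> tuple[dict[str, str], dict[str, str], list[MotifPlacement]]:
    """Promoter sequences with planted binding elements.

    Returns ``(promoters, tf_motifs, placements)``.  Every planted TF-target
    promoter carries >= 1 exact instance of its TF's motif at a random
    offset/strand; every other promoter is rejection-sampled against all
    instantiated motifs, so motif presence <=> planted regulation.
    Promoters are in gene orientation (what
    :func:`lmrnet.tf.extract_promoter` returns).
    """
    if len(motif_consensus) >= promoter_length:
        raise SimulationError("motif must be shorter than the promoter")
    rng = np.random.default_rng([seed, 1])
    tf_ids = sorted({f.id for f in annotation.genes(roles=("TF",))})
    motifs = instantiate_motifs(tf_ids, motif_consensus, rng)
    motif_list = sorted(set(motifs.values()))
    targets_of: dict[str, str] = {}
    for e in tf_edges:
        if e.mechanism == "tf_binding":
            targets_of.setdefault(e.target_id, e.source_id)

    promoters: dict[str, str] = {}
    placements: list[MotifPlacement] = []
    genes = sorted(annotation.genes(roles=("mRNA", "TF")), key=lambda g: g.start)
    for g in genes:
        seq = None
        for _ in range(100):
            cand = _random_seq(rng, promoter_length)
            if not motif_list or not _contains_any_motif(cand, motif_list):
                seq = cand
                break
        if seq is None:
            raise SimulationError(
                f"could not sample a motif-free promoter for {g.id} after 100 "
                f"tries; the consensus {motif_consensus!r} is too permissive"
            )
        if plant and g.id in targets_of:
            motif = motifs[targets_of[g.id]]
            offset = int(rng.integers(0, promoter_length - len(motif) + 1))
            strand = str(rng.choice(np.array(["+", "-"])))
            inserted = motif if strand == "+" else reverse_complement(motif)
            seq = seq[:offset] + inserted + seq[offset + len(motif) :]
            placements.append(MotifPlacement(g.id, offset, strand))
        promoters[g.id] = seq
    return promoters, motifs, placements


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _direction_basis(n_conditions: int) -> np.ndarray:
    """Orthonormal basis (2 x n) of the centered-trajectory plane."""
    from scipy.linalg import helmert

    h = helmert(n_conditions)
    if n_conditions == 2:
        return np.vstack([h[0], np.zeros_like(h[0])])
    return h[:2]


def _trajectories(
    cfg: SimulationConfig, plan: _Plan
) -> dict[str, np.ndarray]:
    """Per-feature latent log2 condition trajectories (centered).

    Regulators carry the intrinsic condition response; targets inherit it
    scaled by ``target_correlation`` (sign-flipped for miRNA and trans-lncRNA
    mechanisms).  Unplanted features are flat.
    """
    basis = _direction_basis(cfg.n_conditions)

    def v(theta_deg: float) -> np.ndarray:
        # unit vector in the centered plane; per-condition trajectory
        # variance is then amplitude^2 / n_conditions
        t = math.radians(theta_deg)
        return math.cos(t) * basis[0] + math.sin(t) * basis[1]

    tc = cfg.target_correlation
    traj: dict[str, np.ndarray] = {}

    def set_regulator(src: str, theta: float, amp: float) -> float:
        if src not in traj:
            traj[src] = amp * v(theta)
            traj[src + "__theta"] = np.array([theta])  # bookkeeping, stripped later
        return float(traj[src + "__theta"][0])

    for e in plan.tf_edges:
        theta = set_regulator(e.source_id, CLUSTER_DIR_DEG, AMPLITUDE["tf_binding"])
        traj[e.target_id] = tc * AMPLITUDE["tf_binding"] * v(theta)
    for e in plan.mirna_edges:
        theta = set_regulator(
            e.source_id, MIRNA_SRC_DIR_DEG, AMPLITUDE["mirna_cleavage_src"]
        )
        # target anti-varies with its miRNA (cleavage) at the cluster dir
        traj[e.target_id] = -tc * AMPLITUDE["mirna_cleavage"] * v(theta)
    for e in plan.cis_edges:
        # the cis lncRNA itself stays flat (see module constants); its
        # target gene responds to the conditions at the cluster direction
        traj[e.target_id] = tc * AMPLITUDE["lnc_cis"] * v(CLUSTER_DIR_DEG)
    for i, e in enumerate(plan.trans_edges):
        theta = set_regulator(
            e.source_id,
            (TRANS_SPACING_DEG * i + 180.0) % 360.0,
            AMPLITUDE["lnc_trans"],
        )
        traj[e.target_id] = -tc * AMPLITUDE["lnc_trans"] * v(theta)

    return {k: val for k, val in traj.items() if not k.endswith("__theta")}


def generate_expression(
    cfg: SimulationConfig, plan: _Plan | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict[str, np.ndarray]]:
    """Negative-binomial count matrices around the latent trajectories.

    Returns ``(mrna_matrix, mirna_matrix, trajectories)`` where the first
    matrix stacks mRNA + TF + lncRNA features.  Counts ~ NB(mean, shared
    dispersion) with mean 2^(baseline + trajectory).
    """
    cfg.validate()
    if cfg.nb_dispersion <= 0:  # validate() covers this; keep explicit contract
        raise SimulationError("nb_dispersion must be positive")
    if plan is None:
        plan = _plan(cfg)
    rng = np.random.default_rng([cfg.seed, 3])
    traj = _trajectories(cfg, plan)
    conds = cfg.conditions()
    samples = [f"{c}_r{r + 1}" for c in conds for r in range(cfg.n_replicates)]
    cond_of = {s: s.rsplit("_r", 1)[0] for s in samples}
    cond_idx = np.array([conds.index(cond_of[s]) for s in samples])

    def build(feature_ids: list[str], roles: dict[str, str]) -> ExpressionMatrix:
        lo, hi = cfg.baseline_mean_log_range
        blo, bhi = cfg.background_mean_log_range
        u = rng.uniform(0.0, 1.0, size=len(feature_ids))
        planted = np.array([f in traj for f in feature_ids])
        base = np.where(planted, lo + (hi - lo) * u, blo + (bhi - blo) * u)
        tr = np.stack(
            [traj.get(f, np.zeros(cfg.n_conditions)) for f in feature_ids]
        )
        log2_mean = base[:, None] + tr[:, cond_idx]
        mean = np.power(2.0, log2_mean)
        # FPKM/TPM are relative abundances, so a condition-dependent library
        # composition would leak a common-mode trajectory into every
        # feature.  The flat background bulk absorbs the per-condition mass
        # deficit proportionally, keeping the expected composition constant
        # (the standard "most of the transcriptome is unchanged"
        # assumption); because the bulk is large, the induced per-feature
        # swing stays far below the differential-call thresholds.
        flat_rows = np.flatnonzero(~planted)
        if flat_rows.size:
            totals = mean.sum(axis=0)
            bulk = mean[flat_rows].sum(axis=0)
            mean[flat_rows] *= 1.0 + (totals.max() - totals) / bulk
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
        return ExpressionMatrix(
            data=pd.DataFrame(counts, index=feature_ids, columns=samples),
            roles=roles,
            conditions=dict(cond_of),
            unit="raw_count",
        )

    mrna_ids = plan.gene_ids + plan.tf_ids + plan.lnc_ids
    roles = (
        {g: "mRNA" for g in plan.gene_ids}
        | {t: "TF" for t in plan.tf_ids}
        | {l: "lncRNA" for l in plan.lnc_ids}
    )
    mrna = build(mrna_ids, roles)
    mirna = build(plan.mirna_ids, {m: "miRNA" for m in plan.mirna_ids})
    return mrna, mirna, traj


def _expected_de(
    cfg: SimulationConfig, traj: Mapping[str, np.ndarray]
) -> list[str]:
    """Features whose latent trajectory differs >= 2-fold between condition 1
    and some other condition."""
    out = []
    for fid in sorted(traj):
        t = traj[fid]
        if np.max(np.abs(t[0] - t[1:])) >= 1.0 - 1e-9:
            out.append(fid)
    return out


# ---------------------------------------------------------------------------
# Full fixture
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    genome: str
    counts: ExpressionMatrix  # mRNA + TF + lncRNA
    mirna_counts: ExpressionMatrix
    mirna_seqs: dict[str, str]
    transcript_seqs: dict[str, str]  # keyed by gene id (spliced transcript)
    lnc_seqs: dict[str, str]
    promoters: dict[str, str]
    tf_motifs: dict[str, str]
    truth: GroundTruth
    trajectories: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def role_map(self) -> dict[str, str]:
        return dict(self.counts.roles) | dict(self.mirna_counts.roles)


def _seq_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return codes


def _write_into_exons(
    genome: np.ndarray, exons: list[tuple[int, int]], strand: str, seq: str
) -> None:
    codes = _seq_codes(seq)
    if strand == "-":
        codes = (3 - codes)[::-1]
    pos = 0
    for s, e in exons:
        n = e - s
        genome[s:e] = codes[pos : pos + n]
        pos += n
    assert pos == len(codes)


def _spliced_seq(genome_str: str, feature: FeatureModel) -> str:
    parts = [genome_str[s:e] for s, e in (feature.exons or [(feature.start, feature.end)])]
    seq = "".join(parts)
    return reverse_complement(seq) if feature.strand == "-" else seq


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full in-memory fixture bundle for one (config, seed)."""
    cfg.validate()
    plan = _plan(cfg)
    annotation = generate_annotation(cfg)
    promoters, tf_motifs, placements = plant_motifs(
        annotation,
        cfg.motif_consensus,
        plan.tf_edges,
        cfg.seed,
        cfg.promoter_length,
        plant=cfg.plant_motifs,
    )

    rng_seq = np.random.default_rng([cfg.seed, 2])
    # miRNA sequences first: needed to embed target sites.  The first two
    # decoy miRNAs get out-of-range lengths (17 / 31 nt) so fixtures exercise
    # the small-RNA length filter.
    planted_mirnas = sorted({e.source_id for e in plan.mirna_edges})
    mirna_seqs: dict[str, str] = {}
    decoy_rank = 0
    for mid in plan.mirna_ids:
        if mid in planted_mirnas:
            length = cfg.mirna_length
        else:
            length = {0: 17, 1: 31}.get(decoy_rank, cfg.mirna_length)
            decoy_rank += 1
        mirna_seqs[mid] = _random_seq(rng_seq, length)

    site_of: dict[str, str] = {}  # target gene -> site sequence to embed
    for e in plan.mirna_edges:
        site_of[e.target_id] = reverse_complement(mirna_seqs[e.source_id])

    tx_len = sum(e - s for s, e in EXONS_REL)
    transcript_content: dict[str, str] = {}
    for gid in plan.gene_ids + plan.tf_ids:
        seq = _random_seq(rng_seq, tx_len)
        if gid in site_of:
            site = site_of[gid]
            pos = int(rng_seq.integers(50, tx_len - 50 - len(site)))
            seq = seq[:pos] + site + seq[pos + len(site) :]
        transcript_content[gid] = seq

    lnc_content: dict[str, str] = {}
    for lid in plan.lnc_ids:
        lnc_len = annotation[lid].length
        for _ in range(200):
            seq = _random_seq(rng_seq, lnc_len)
            if longest_orf_aa(seq) < 100:
                lnc_content[lid] = seq
                break
        else:
            raise SimulationError(f"could not sample a non-coding sequence for {lid}")

    # --- genome assembly ---------------------------------------------------
    required = _required_length(cfg, plan)
    length = cfg.chrom_length if cfg.chrom_length is not None else required
    rng_bg = np.random.default_rng([cfg.seed, 4])
    genome = rng_bg.integers(0, 4, size=length).astype(np.uint8)

    by_id = {f.id: f for f in annotation.features}
    for gid, seq in transcript_content.items():
        t = by_id[f"{gid}.t1"]
        _write_into_exons(genome, t.exons, t.strand, seq)
    for lid, seq in lnc_content.items():
        t = by_id[lid]
        _write_into_exons(genome, t.exons, t.strand, seq)
    for gid, prom in promoters.items():
        g = by_id[gid]
        codes = _seq_codes(prom)
        if g.strand == "+":
            genome[g.start - len(prom) : g.start] = codes
        else:
            genome[g.end : g.end + len(prom)] = (3 - codes)[::-1]

    genome_str = _BASES[genome].tobytes().decode()

    # re-derive all emitted sequences from the final genome so annotation,
    # genome and FASTA files are consistent by construction
    transcript_seqs = {
        gid: _spliced_seq(genome_str, by_id[f"{gid}.t1"])
        for gid in plan.gene_ids + plan.tf_ids
    }
    lnc_seqs = {lid: _spliced_seq(genome_str, by_id[lid]) for lid in plan.lnc_ids}
    promoters_final = {
        gid: extract_promoter(by_id[gid], genome_str, cfg.promoter_length)
        for gid in plan.gene_ids + plan.tf_ids
    }

    mrna, mirna, traj = generate_expression(cfg, plan)
    truth = GroundTruth(
        edges=plan.edges,
        motif_placements=placements,
        expected_de_features=_expected_de(cfg, traj),
    )
    return SimulatedDataset(
        config=cfg,
        annotation=annotation,
        genome=genome_str,
        counts=mrna,
        mirna_counts=mirna,
        mirna_seqs=mirna_seqs,
        transcript_seqs=transcript_seqs,
        lnc_seqs=lnc_seqs,
        promoters=promoters_final,
        tf_motifs=tf_motifs,
        truth=truth,
        trajectories=traj,
    )


FIXTURE_FILES = {
    "genome": "genome.fa",
    "annotation": "annotation.gff3",
    "counts": "counts.tsv",
    "mirna_counts": "mirna_counts.tsv",
    "samples": "samples.tsv",
    "roles": "roles.tsv",
    "mirna_fasta": "mirna.fa",
    "transcripts_fasta": "transcripts.fa",
    "lncrna_fasta": "lncrna.fa",
    "promoters_fasta": "promoters.fa",
    "tf_motifs": "tf_motifs.tsv",
    "truth_edges": "truth_edges.tsv",
    "truth_motifs": "truth_motifs.tsv",
    "expected_de": "expected_de.tsv",
}


def write_fixture(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture bundle; byte-identical for identical
    (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in FIXTURE_FILES.items()}

    write_fasta({"chr1": ds.genome}, paths["genome"])
    write_gff3(ds.annotation, paths["annotation"])
    write_counts(ds.counts, paths["counts"])
    write_counts(ds.mirna_counts, paths["mirna_counts"])
    write_sample_sheet(ds.counts.conditions, paths["samples"])
    write_roles(ds.role_map, paths["roles"])
    write_fasta(ds.mirna_seqs, paths["mirna_fasta"])
    write_fasta(ds.transcript_seqs, paths["transcripts_fasta"])
    write_fasta(ds.lnc_seqs, paths["lncrna_fasta"])
    write_fasta(ds.promoters, paths["promoters_fasta"])
    pd.DataFrame(
        {"tf_id": list(ds.tf_motifs), "motif": list(ds.tf_motifs.values())}
    ).to_csv(paths["tf_motifs"], sep="\t", index=False)
    pd.DataFrame(
        ds.truth.edges, columns=["source_id", "target_id", "mechanism"]
    ).to_csv(paths["truth_edges"], sep="\t", index=False)
    pd.DataFrame(
        ds.truth.motif_placements, columns=["gene_id", "offset", "strand"]
    ).to_csv(paths["truth_motifs"], sep="\t", index=False)
    pd.DataFrame({"feature_id": ds.truth.expected_de_features}).to_csv(
        paths["expected_de"], sep="\t", index=False
    )
    return paths


def read_truth_edges(path: str | Path) -> set[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        (r.source_id, r.target_id, r.mechanism) for r in df.itertuples()
    }
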