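"""One-command orchestration: simulate -> quantify -> DE -> targets -> network.

Stages run in a fixed order; every stage writes its TSV output into the
output directory and records a row count in the run manifest.  Outputs are
pure functions of (inputs, config, seed): rerunning an identical config
reproduces byte-identical files.  Any stage error aborts the run with the
stage name; partial outputs are kept and the manifest carries a FAILED
marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import __version__
from .de import DECalls, de_all_contrasts, fpkm, tpm
from .io import (
    ExpressionMatrix,
    GenomeAnnotation,
    read_counts,
    read_fasta,
    read_gff3,
    read_roles,
    read_sample_sheet,
)
from .lncrna import (
    CisWindow,
    cis_targets,
    classify_all,
    filter_lncrna_candidates,
    trans_targets,
)
from .mirna import (
    ScoringConfig,
    coherence_of_calls,
    filter_small_rna,
    predict_targets,
    sites_to_frame,
)
from .network import (
    RegulatoryEdge,
    RegulatoryNetwork,
    assemble_network,
    export_network,
    recovery_metrics,
)
from .sim import SimulationConfig, read_truth_edges, simulate, write_fixture
from .tf import extract_promoter, pairs_to_frame, read_motif_table, tf_gene_pairs

log = logging.getLogger(__name__)

_INPUT_KEYS = (
    "annotation",
    "genome",
    "counts",
    "samples",
    "roles",
    "mirna_counts",
    "mirna_fasta",
    "transcripts_fasta",
    "lncrna_fasta",
    "tf_motifs",
    "truth_edges",  # optional
)
_REQUIRED_INPUTS = tuple(k for k in _INPUT_KEYS if k != "truth_edges")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs (or a simulate block) plus every
    threshold the method applies, each at its standard default."""

    outdir: str | Path = "lmrnet_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] | None = None

    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    pcc_threshold: float = 0.8
    p_threshold: float = 0.05
    trans_r_threshold: float = 0.9
    cis_window_bp: int = 10_000
    mirna_cutoff: float = 4.0
    promoter_length: int = 2000
    small_rna_min: int = 18
    small_rna_max: int = 30
    pseudocount: float = 1.0
    min_lnc_length: int = 200
    max_lnc_orf_aa: int = 100
    trans_correlation_mode: str = "anticorrelated"
    require_motif: bool = True

    def validate(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        for name in ("fdr_threshold", "p_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        for name in ("pcc_threshold", "trans_r_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.cis_window_bp <= 0 or self.promoter_length <= 0:
            raise ValueError("cis_window_bp and promoter_length must be > 0")
        if self.mirna_cutoff < 0 or self.pseudocount <= 0:
            raise ValueError("mirna_cutoff must be >= 0 and pseudocount > 0")
        if not 0 < self.small_rna_min <= self.small_rna_max:
            raise ValueError("need 0 < small_rna_min <= small_rna_max")
        if self.trans_correlation_mode not in ("anticorrelated", "absolute"):
            raise ValueError(
                f"unknown trans_correlation_mode {self.trans_correlation_mode!r}"
            )
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("provide exactly one of `simulate` or `inputs`")
        if self.inputs is not None:
            missing = [k for k in _REQUIRED_INPUTS if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input paths: {missing}")
            absent = [
                f"{k}={v}" for k, v in self.inputs.items() if not Path(v).exists()
            ]
            if absent:
                raise ValueError(f"input files not found: {absent}")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("simulate"), dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(raw["simulate"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
            sim = dict(raw["simulate"])
            if "baseline_mean_log_range" in sim:
                sim["baseline_mean_log_range"] = tuple(sim["baseline_mean_log_range"])
            raw["simulate"] = SimulationConfig(**sim)
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def canonical_json(self) -> str:
        """Configuration serialization for the manifest hash; the output
        location is not part of the scientific configuration."""
        d = dataclasses.asdict(self)
        d.pop("outdir", None)
        return json.dumps(d, sort_keys=True, default=str)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class _Inputs:
    annotation: GenomeAnnotation
    genome: dict[str, str]
    counts: ExpressionMatrix
    mirna_counts: ExpressionMatrix
    mirna_seqs: dict[str, str]
    transcript_seqs: dict[str, str]
    lnc_seqs: dict[str, str]
    tf_motifs: dict[str, str]
    truth: set[tuple[str, str, str]] | None
    promoters: dict[str, str] | None = None


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    network: RegulatoryNetwork | None = None
    recovery: dict | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def gene_lengths_for_counts(annotation: GenomeAnnotation) -> dict[str, int]:
    """Spliced transcript length per countable feature id.

    Transcript lengths roll up to their parent gene id (longest isoform if
    several); standalone transcripts (lncRNAs) keep their own id.
    """
    lengths: dict[str, int] = {}
    for t in annotation.transcripts():
        key = t.parent_id or t.id
        lengths[key] = max(lengths.get(key, 0), t.length)
    for g in annotation.genes():
        lengths.setdefault(g.id, g.length)
    return lengths


def _load_inputs(cfg: PipelineConfig, outdir: Path) -> _Inputs:
    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        ds = simulate(sim_cfg)
        write_fixture(ds, outdir / "fixture")
        return _Inputs(
            annotation=ds.annotation,
            genome={"chr1": ds.genome},
            counts=ds.counts,
            mirna_counts=ds.mirna_counts,
            mirna_seqs=ds.mirna_seqs,
            transcript_seqs=ds.transcript_seqs,
            lnc_seqs=ds.lnc_seqs,
            tf_motifs=ds.tf_motifs,
            truth=ds.truth.edge_keys(),
            promoters=ds.promoters,
        )
    paths = {k: Path(v) for k, v in cfg.inputs.items()}
    annotation = read_gff3(paths["annotation"])
    conditions = read_sample_sheet(paths["samples"])
    roles = read_roles(paths["roles"])
    counts = read_counts(paths["counts"], conditions, roles)
    mirna_counts = read_counts(paths["mirna_counts"], conditions, roles)
    motif_df = read_motif_table(paths["tf_motifs"])
    truth = (
        read_truth_edges(paths["truth_edges"]) if "truth_edges" in paths else None
    )
    return _Inputs(
        annotation=annotation,
        genome=read_fasta(paths["genome"]),
        counts=counts,
        mirna_counts=mirna_counts,
        mirna_seqs=read_fasta(paths["mirna_fasta"]),
        transcript_seqs=read_fasta(paths["transcripts_fasta"]),
        lnc_seqs=read_fasta(paths["lncrna_fasta"]),
        tf_motifs={k: m.iupac_consensus for k, m in motif_df.items()},
        truth=truth,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute all stages; see the module docstring for the contract."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg.sha256(),
        "stages": [],
        "status": "OK",
    }
    result = PipelineResult(outdir=outdir, manifest=manifest)
    state: dict[str, Any] = {}

    def run_stage(name: str, fn: Callable[[], int]) -> None:
        t0 = time.monotonic()
        try:
            rows = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "FAILED", "rows": 0})
            manifest["status"] = "FAILED"
            _write_manifest(manifest, outdir)
            raise PipelineError(name, exc) from exc
        log.info("stage %-22s %6d rows  (%.2fs)", name, rows, time.monotonic() - t0)
        manifest["stages"].append({"name": name, "status": "OK", "rows": rows})

    def save(name: str, df: pd.DataFrame) -> None:
        result.tables[name] = df
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")

    # -- load ---------------------------------------------------------------
    def stage_load() -> int:
        state["in"] = _load_inputs(cfg, outdir)
        return len(state["in"].counts.feature_ids)

    run_stage("load_inputs", stage_load)
    inp: _Inputs = state["in"]

    # -- normalize ----------------------------------------------------------
    def stage_normalize() -> int:
        lengths = gene_lengths_for_counts(inp.annotation)
        state["fpkm"] = fpkm(inp.counts, lengths)
        state["tpm"] = tpm(inp.mirna_counts)
        return len(state["fpkm"].feature_ids) + len(state["tpm"].feature_ids)

    run_stage("normalize", stage_normalize)

    # -- differential expression -------------------------------------------
    def stage_de() -> int:
        de_m = de_all_contrasts(
            state["fpkm"], cfg.fc_threshold, cfg.fdr_threshold, cfg.pseudocount
        )
        de_mi = de_all_contrasts(
            state["tpm"], cfg.fc_threshold, cfg.fdr_threshold, cfg.pseudocount
        )
        save("de_mrna", de_m)
        save("de_mirna", de_mi)
        state["calls_m"] = DECalls(de_m)
        state["calls_mi"] = DECalls(de_mi)
        return int((de_m["call"] != "ns").sum() + (de_mi["call"] != "ns").sum())

    run_stage("differential_expression", stage_de)
    calls_m: DECalls = state["calls_m"]
    calls_mi: DECalls = state["calls_mi"]

    # -- lncRNA stage -------------------------------------------------------
    def stage_lncrna() -> int:
        lnc_ids = [f for f, r in inp.counts.roles.items() if r == "lncRNA"]
        retained = filter_lncrna_candidates(
            lnc_ids, inp.lnc_seqs, cfg.min_lnc_length, cfg.max_lnc_orf_aa
        )
        state["lnc_retained"] = retained
        classes = classify_all(inp.annotation)
        classes["retained"] = classes["lnc_id"].isin(set(retained))
        save("lnc_classes", classes)

        # cis targeting is positional: every retained lncRNA is screened
        # against its 10-kb neighborhood, keeping genes that respond to the
        # conditions (DEG filter); the lncRNA's own differential status is
        # deliberately not required (trans targeting covers the
        # expression-based evidence).
        window = CisWindow(cfg.cis_window_bp)
        rows = []
        for lid in retained:
            if lid not in inp.annotation:
                continue
            for gid in cis_targets(inp.annotation[lid], inp.annotation, window):
                if calls_m.is_de(gid):
                    rows.append((lid, gid))
        cis_df = pd.DataFrame(rows, columns=["lnc_id", "gene_id"])
        save("cis_pairs", cis_df)
        state["cis_pairs"] = cis_df

        lnc_expr = state["fpkm"].subset_features(retained)
        mrna_expr = state["fpkm"].subset_roles(["mRNA", "TF"])
        trans_df = trans_targets(
            lnc_expr,
            mrna_expr,
            calls_m,
            r_threshold=cfg.trans_r_threshold,
            mode=cfg.trans_correlation_mode,
        )
        save("trans_pairs", trans_df)
        state["trans_pairs"] = trans_df
        return len(cis_df) + len(trans_df)

    run_stage("lncrna_targets", stage_lncrna)

    # -- miRNA stage --------------------------------------------------------
    def stage_mirna() -> int:
        kept = filter_small_rna(
            inp.mirna_seqs, cfg.small_rna_min, cfg.small_rna_max
        )
        dems = {m: s for m, s in kept.items() if calls_mi.is_de(m)}
        sites = predict_targets(
            dems,
            inp.transcript_seqs,
            cutoff=cfg.mirna_cutoff,
            config=ScoringConfig(cutoff=cfg.mirna_cutoff),
        )
        save("mirna_sites", sites_to_frame(sites))
        pair_rows = []
        edge_rows = []
        for s in sites:
            shared = [
                c
                for c in calls_mi.contrasts
                if calls_mi.call(s.mirna_id, c) != "ns"
                and calls_m.call(s.transcript_id, c) != "ns"
            ]
            cohs = []
            for c in shared:
                coh = coherence_of_calls(
                    calls_mi.call(s.mirna_id, c), calls_m.call(s.transcript_id, c)
                )
                pair_rows.append((s.mirna_id, s.transcript_id, c, coh))
                cohs.append(coh)
            if shared:
                overall = "coherent" if "coherent" in cohs else "noncoherent"
                edge_rows.append((s, overall))
        save(
            "mirna_pairs",
            pd.DataFrame(
                pair_rows, columns=["mirna_id", "target_id", "contrast", "coherence"]
            ),
        )
        state["mirna_edges"] = edge_rows
        return len(edge_rows)

    run_stage("mirna_targets", stage_mirna)

    # -- TF stage -----------------------------------------------------------
    def stage_tf() -> int:
        if inp.promoters is not None:
            promoters = inp.promoters
        else:
            promoters = {}
            for g in inp.annotation.genes(roles=("mRNA", "TF")):
                promoters[g.id] = extract_promoter(
                    g, inp.genome[g.chrom], cfg.promoter_length
                )
        from .tf import MotifModel

        motifs = {
            t: MotifModel(name=f"{t}_motif", iupac_consensus=m)
            for t, m in inp.tf_motifs.items()
        }
        pairs = tf_gene_pairs(
            state["fpkm"].subset_roles(["TF"]),
            state["fpkm"].subset_roles(["mRNA", "TF"]),
            calls_m,
            promoters,
            motifs,
            pcc_threshold=cfg.pcc_threshold,
            p_threshold=cfg.p_threshold,
            require_motif=cfg.require_motif,
        )
        save("tf_pairs", pairs_to_frame(pairs))
        state["tf_pairs"] = [p for p in pairs if p.accepted]
        return len(state["tf_pairs"])

    run_stage("tf_pairs", stage_tf)

    # -- network ------------------------------------------------------------
    def stage_network() -> int:
        edges: list[RegulatoryEdge] = []
        for p in state["tf_pairs"]:
            edges.append(
                RegulatoryEdge(
                    p.tf_id,
                    p.gene_id,
                    "tf_binding",
                    evidence={"pcc": p.pcc, "pcc_p": p.pcc_p, "motif_hits": p.motif_hits},
                )
            )
        for s, coh in state["mirna_edges"]:
            edges.append(
                RegulatoryEdge(
                    s.mirna_id,
                    s.transcript_id,
                    "mirna_cleavage",
                    evidence={"penalty_score": s.penalty_score, "coherence": coh},
                )
            )
        for row in state["cis_pairs"].itertuples():
            edges.append(RegulatoryEdge(row.lnc_id, row.gene_id, "lnc_cis"))
        for row in state["trans_pairs"].itertuples():
            edges.append(
                RegulatoryEdge(
                    row.lnc_id, row.gene_id, "lnc_trans", evidence={"pcc": row.pcc}
                )
            )
        role_map = dict(inp.counts.roles) | dict(inp.mirna_counts.roles)
        net = assemble_network(edges, role_map)
        result.network = net
        export_network(net, outdir / "network_edges.tsv", "TSV")
        export_network(net, outdir / "network.sif", "SIF")
        export_network(net, outdir / "network.graphml", "GraphML")
        return len(net.edges)

    run_stage("assemble_network", stage_network)

    # -- recovery -----------------------------------------------------------
    if inp.truth is not None:

        def stage_recovery() -> int:
            metrics = recovery_metrics(result.network, inp.truth)
            result.recovery = metrics
            rows = [
                {"mechanism": mech, **vals} for mech, vals in metrics.items()
            ]
            save("recovery", pd.DataFrame(rows))
            return len(rows)

        run_stage("recovery", stage_recovery)

    _write_manifest(manifest, outdir)
    return result


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
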