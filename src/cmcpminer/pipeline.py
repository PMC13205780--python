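"""End-to-end orchestration of the CMCP discovery stages.

Stage DAG::

    simulate -> build-models / curate -> mine -> quantify -> diff -> meta
                                   similarity (leaf)

Every stage reads the artifacts of its predecessors from the output
directory, writes its own artifacts in plain TSV/FASTA/JSON, and drops
a provenance record (parameters, seed, input checksums, record counts)
next to them.  Reruns with the same configuration and seed reproduce
the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from cmcpminer import __version__
from cmcpminer.abundance import CohortStats, diff_abundance
from cmcpminer.curation import CytokineFamily, curate_family
from cmcpminer.meta_analysis import classify_enrichment, write_meta_table
from cmcpminer.mining import attach_provenance, scan_proteins, write_clusters_table, write_hits_table
from cmcpminer.msa import progressive_align
from cmcpminer.profile_hmm import ProfileHMM, build_profile, calibrate
from cmcpminer.seq_io import SequenceRecord, extract_orfs, read_fasta, write_fasta
from cmcpminer.similarity import local_align_identity, select_representative, write_similarity_table
from cmcpminer.synthetic_data import SimScenario, simulate_cohorts, simulate_family, simulate_genome


log = logging.getLogger("cmcpminer")

STAGES = ("simulate", "build-models", "curate", "mine", "quantify",
          "diff", "meta", "similarity")


@dataclass
class PipelineConfig:
    """Thresholds and paths governing a pipeline run.

    Threshold defaults: hits kept at E < 0.01; curation target mean
    fold accuracy 0.5 with K = 10 folds; clustering at 95% identity
    with 90% coverage of the shorter sequence; ORFs >= 150 nt;
    significance cut-off 0.05; volcano highlight |LFC| > 2 & padj < 0.05.
    """

    out_dir: str = "cmcp_out"
    seed: int = 0
    evalue_max: float = 0.01
    cv_target: float = 0.5
    K: int = 10
    identity_c: float = 0.95
    aS: float = 0.9
    min_nt: int = 150
    alpha: float = 0.05
    lfc_highlight: float = 2.0
    calibration_decoys: int = 500
    scenario: dict = field(default_factory=dict)
    families_dir: Optional[str] = None
    contigs_path: Optional[str] = None
    counts_path: Optional[str] = None
    meta_path: Optional[str] = None
    human_refs_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.evalue_max:
            raise ValueError("evalue_max must be positive")
        if not 0 <= self.cv_target <= 1:
            raise ValueError("cv_target must lie in [0, 1]")
        if not 0 < self.identity_c <= 1 or not 0 < self.aS <= 1:
            raise ValueError("clustering thresholds must lie in (0, 1]")
        if self.min_nt < 3 or self.min_nt % 3:
            raise ValueError("min_nt must be a positive multiple of 3")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


def _checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _provenance(cfg: PipelineConfig, stage: str, inputs: list[Path],
                counts: dict[str, int]) -> None:
    rec = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()
                       if not isinstance(v, dict)},
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
        "record_counts": counts,
    }
    path = cfg.out / "provenance" / f"{stage}.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(rec, indent=2, sort_keys=True))
    log.info("stage=%s %s", stage,
             " ".join(f"{k}={v}" for k, v in counts.items()))


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path}; run stage {produced_by!r} first"
        )
    return path


def _load_families(cfg: PipelineConfig, subdir: str) -> list[CytokineFamily]:
    fam_dir = (Path(cfg.families_dir) if cfg.families_dir and subdir == "families"
               else cfg.out / subdir)
    fastas = sorted(fam_dir.glob("*.fasta"))
    if not fastas:
        raise FileNotFoundError(
            f"no family FASTA files in {fam_dir}; run stage 'simulate' "
            f"or point families_dir at your data"
        )
    return [CytokineFamily(p.stem, read_fasta(p)) for p in fastas]


def stage_simulate(cfg: PipelineConfig) -> None:
    scenario = SimScenario(seed=cfg.seed, **cfg.scenario)
    out = cfg.out
    (out / "families").mkdir(parents=True, exist_ok=True)
    truth = {}
    refs = []
    families = []
    for i in range(scenario.n_families):
        name = f"fam{i + 1}"
        fam, fam_truth = simulate_family(scenario, name=name, family_index=i)
        write_fasta(fam.members, out / "families" / f"{name}.fasta")
        truth[name] = fam_truth.confounder_ids
        refs.append(SequenceRecord(id=f"{name}_ref", residues=fam_truth.root_protein))
        families.append(fam)
    (out / "truth_confounders.json").write_text(json.dumps(truth, indent=2))
    write_fasta(refs, out / "human_refs.fasta")
    contigs, orf_truth = simulate_genome(scenario, families)
    write_fasta(contigs, out / "contigs.fasta")
    orf_truth.to_csv(out / "truth_orfs.tsv", sep="\t", index=False)
    counts, meta, effects = simulate_cohorts(scenario)
    counts.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "sample_meta.tsv", sep="\t")
    (out / "truth_effects.json").write_text(json.dumps(effects, indent=2))
    _provenance(cfg, "simulate", [], {
        "families": scenario.n_families,
        "contigs": len(contigs),
        "samples": counts.shape[1],
        "features": counts.shape[0],
    })


def _build_and_calibrate(fam: CytokineFamily, cfg: PipelineConfig) -> ProfileHMM:
    aln = progressive_align(fam.members, family=fam.name)
    hmm = build_profile(aln)
    decoy_len = int(pd.Series([len(m) for m in fam.members]).median())
    calibrate(hmm, decoy_length=decoy_len, n_decoys=cfg.calibration_decoys,
              seed=cfg.seed)
    return hmm


def stage_build_models(cfg: PipelineConfig) -> None:
    families = _load_families(cfg, "families")
    model_dir = cfg.out / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    for fam in families:
        hmm = _build_and_calibrate(fam, cfg)
        hmm.save(model_dir / f"{fam.name}.json")
    _provenance(cfg, "build-models",
                sorted((cfg.out / "families").glob("*.fasta")),
                {"models": len(families)})


def stage_curate(cfg: PipelineConfig) -> None:
    families = _load_families(cfg, "families")
    cur_dir = cfg.out / "curated"
    rep_dir = cfg.out / "curation_reports"
    model_dir = cfg.out / "models"
    for d in (cur_dir, rep_dir, model_dir):
        d.mkdir(parents=True, exist_ok=True)
    kept = 0
    for fam in families:
        curated, report = curate_family(
            fam, target_accuracy=cfg.cv_target, K=cfg.K,
            evalue_max=cfg.evalue_max, seed=cfg.seed,
            calibration_decoys=cfg.calibration_decoys,
        )
        (rep_dir / f"{fam.name}.json").write_text(report.to_json())
        if report.converged:
            write_fasta(curated.members, cur_dir / f"{fam.name}.fasta")
            hmm = _build_and_calibrate(curated, cfg)
            hmm.save(model_dir / f"{fam.name}.json")
            kept += 1
        else:
            log.warning("family %s rejected: %s", fam.name, report.reason)
    _provenance(cfg, "curate",
                sorted((cfg.out / "families").glob("*.fasta")),
                {"families_in": len(families), "families_kept": kept})


def stage_mine(cfg: PipelineConfig) -> None:
    contigs_path = Path(cfg.contigs_path) if cfg.contigs_path else cfg.out / "contigs.fasta"
    _require(contigs_path, "mine", "simulate")
    model_paths = sorted((cfg.out / "models").glob("*.json"))
    if not model_paths:
        raise FileNotFoundError(
            f"no models under {cfg.out / 'models'}; run stage "
            f"'build-models' or 'curate' first"
        )
    models = [ProfileHMM.load(p) for p in model_paths]
    contigs = read_fasta(contigs_path, alphabet="dna")
    orfs = [o for c in contigs for o in extract_orfs(c, min_nt=cfg.min_nt)]
    proteins = [o.protein for o in orfs]
    hits = scan_proteins(models, proteins, evalue_max=cfg.evalue_max)
    result = attach_provenance(hits, orfs, identity_c=cfg.identity_c,
                               short_coverage_aS=cfg.aS)
    write_hits_table(result.hits, cfg.out / "hits.tsv")
    write_clusters_table(result.cluster_membership, cfg.out / "clusters.tsv")
    if result.representatives:
        write_fasta(result.representatives, cfg.out / "representatives.fasta")
    _provenance(cfg, "mine", [contigs_path] + model_paths, {
        "orfs": len(orfs), "hits": len(hits),
        "representatives": len(result.representatives),
    })


def stage_quantify(cfg: PipelineConfig) -> None:
    src = Path(cfg.counts_path) if cfg.counts_path else cfg.out / "counts.tsv"
    _require(src, "quantify", "simulate")
    counts = pd.read_csv(src, sep="\t", index_col=0)
    counts.to_csv(cfg.out / "counts_quantified.tsv", sep="\t")
    _provenance(cfg, "quantify", [src], {
        "features": counts.shape[0], "samples": counts.shape[1]})


def _load_counts_meta(cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts_path = _require(cfg.out / "counts_quantified.tsv", "diff", "quantify")
    meta_path = Path(cfg.meta_path) if cfg.meta_path else cfg.out / "sample_meta.tsv"
    _require(meta_path, "diff", "simulate")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return counts, meta


def stage_diff(cfg: PipelineConfig) -> None:
    counts, meta = _load_counts_meta(cfg)
    diff_dir = cfg.out / "diff"
    diff_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for cohort in sorted(meta["cohort"].unique()):
        stats = diff_abundance(counts, meta, cohort, alpha=cfg.alpha,
                               lfc_highlight=cfg.lfc_highlight)
        out = stats.table.copy()
        out.insert(0, "n_control", stats.n_control)
        out.insert(0, "n_case", stats.n_case)
        out.to_csv(diff_dir / f"{cohort}.tsv", sep="\t", float_format="%.6g")
        n += 1
    _provenance(cfg, "diff", [cfg.out / "counts_quantified.tsv"],
                {"cohorts": n, "features": counts.shape[0]})


def stage_meta(cfg: PipelineConfig) -> None:
    counts, meta = _load_counts_meta(cfg)
    diff_dir = _require(cfg.out / "diff", "meta", "diff")
    cohort_stats = []
    for cohort in sorted(meta["cohort"].unique()):
        path = _require(diff_dir / f"{cohort}.tsv", "meta", "diff")
        table = pd.read_csv(path, sep="\t", index_col=0)
        cohort_stats.append(CohortStats(
            cohort=cohort,
            table=table.drop(columns=["n_case", "n_control"]),
            n_case=int(table["n_case"].iloc[0]),
            n_control=int(table["n_control"].iloc[0]),
        ))
    meta_table = classify_enrichment(cohort_stats, alpha=cfg.alpha)
    write_meta_table(meta_table, cfg.out / "meta.tsv")
    sig = int((meta_table["class"] != "ns").sum()) if len(meta_table) else 0
    _provenance(cfg, "meta", sorted(diff_dir.glob("*.tsv")),
                {"features": len(meta_table), "significant": sig})


def stage_similarity(cfg: PipelineConfig) -> None:
    refs_path = (Path(cfg.human_refs_path) if cfg.human_refs_path
                 else cfg.out / "human_refs.fasta")
    _require(refs_path, "similarity", "simulate")
    refs = {r.id: r for r in read_fasta(refs_path)}
    families = _load_families(cfg, "curated" if (cfg.out / "curated").exists()
                              else "families")
    records = []
    reps = []
    for fam in families:
        ref = refs.get(f"{fam.name}_ref") or next(iter(refs.values()))
        rep = select_representative(fam.members, ref)
        reps.append(rep)
        records.append(local_align_identity(rep, ref))
    write_similarity_table(records, cfg.out / "similarity.tsv")
    write_fasta(reps, cfg.out / "family_representatives.fasta")
    _provenance(cfg, "similarity", [refs_path], {"families": len(records)})


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build-models": stage_build_models,
    "curate": stage_curate,
    "mine": stage_mine,
    "quantify": stage_quantify,
    "diff": stage_diff,
    "meta": stage_meta,
    "similarity": stage_similarity,
}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    """Run one named stage, writing artifacts and a provenance record."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    cfg.out.mkdir(parents=True, exist_ok=True)
    _STAGE_FUNCS[name](cfg)


def run_all(cfg: PipelineConfig) -> None:
    """Run the full DAG: simulate through meta-analysis plus similarity."""
    for name in ("simulate", "curate", "mine", "quantify", "diff", "meta",
                 "similarity"):
        run_stage(name, cfg)
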