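"""Configuration-driven orchestration of the full subtyping pipeline.

Stages run in dependency order -- simulate (optional), select-genes,
cluster, characterize, signatures, enrich, survival -- and communicate only
through serialized artifacts in the output directory. Every run writes a
provenance manifest (input hashes, config snapshot, seeds); reruns with
identical inputs and seeds are bit-identical for deterministic stages.

All the analysis thresholds are surfaced with their study defaults: the
0.001 candidate tail, the 95% dominant-child rule, the 2-15 signature
range, the 0.05 enrichment FDR, and the 1- and 3-mutation load variants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import characterization, clustering, enrichment, gene_selection
from . import signatures as sigmod
from . import survival as survmod
from .io_profiles import (
    CohortMatrix,
    GeneCatalog,
    build_count_matrix,
    filter_coding,
    read_mutations,
)
from .synthetic import SubtypeSpec, SyntheticConfig, generate_cohort

log = logging.getLogger("pansubtypes")

ALL_STAGES = ("simulate", "select-genes", "cluster", "characterize",
              "signatures", "enrich", "survival")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """One pipeline run: inputs, thresholds, seeds, outputs."""

    outdir: str
    # inputs (resolved against outdir/inputs when simulate runs first)
    mutations: str | None = None
    gene_catalog: str | None = None
    clinical: str | None = None
    motif_counts: str | None = None
    genome_fasta: str | None = None
    reference_signatures: str | None = None
    gene_sets: str | None = None
    impact_map: str | None = None
    # synthetic-stage overrides (None disables the simulate stage)
    synthetic: dict | None = None
    # stage toggles
    stages: tuple[str, ...] = ALL_STAGES
    # thresholds, paper defaults
    alpha: float = 0.001
    tail: str = "ge"
    dominant_fraction: float = 0.95
    k_max: int = 9
    min_node: int = 20
    representation: str = "binary"
    n_range: tuple[int, int] = (2, 15)
    nmf_restarts: int = 3
    nmf_bootstrap: int = 5
    enrichment_fdr: float = 0.05
    min_mutations_variants: tuple[int, ...] = (1, 3)
    top: int = 100
    seed: int = 0
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for tup in ("stages", "n_range", "min_mutations_variants"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0.5 <= self.dominant_fraction <= 1:
            raise ConfigError("dominant_fraction must be in [0.5, 1]")
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ConfigError("n_range must be an increasing pair >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages or self.synthetic is None:
            for name in ("mutations", "gene_catalog"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(
                        f"input {name!r} missing or not found: {p}")

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def demo_synthetic_spec(seed: int = 0) -> dict:
    """The small demo study: 240 samples, 1,200 genes, 3 planted subtypes."""
    return {
        "n_samples": 240,
        "n_genes": 1200,
        "n_cancer_types": 2,
        "n_subtypes": 3,
        "genes_per_subtype": 8,
        "elevation_factor": 12.0,
        "motif_mutations_mean": 300.0,
        "seed": seed,
    }


def demo_config(outdir: str | Path, seed: int = 0) -> RunConfig:
    """A self-contained demo run on the synthetic cohort."""
    return RunConfig(
        outdir=str(outdir),
        synthetic=demo_synthetic_spec(seed),
        n_range=(2, 5),
        nmf_restarts=2,
        nmf_bootstrap=3,
        k_max=6,
        seed=seed,
    )


def _synthetic_config(spec: dict) -> SyntheticConfig:
    spec = dict(spec)
    n_subtypes = spec.pop("n_subtypes", 4)
    genes_per = spec.pop("genes_per_subtype", 10)
    elevation = spec.pop("elevation_factor", 10.0)
    if "subtype_spec" not in spec:
        from .synthetic import default_subtype_spec
        spec["subtype_spec"] = default_subtype_spec(
            n_subtypes, genes_per, elevation)
    else:
        spec["subtype_spec"] = tuple(
            SubtypeSpec(**s) for s in spec["subtype_spec"])
    return SyntheticConfig(**spec)


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages and write the provenance manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.snapshot(),
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
    }
    artifacts: dict[str, Path] = {}
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "select-genes": _stage_select_genes,
        "cluster": _stage_cluster,
        "characterize": _stage_characterize,
        "signatures": _stage_signatures,
        "enrich": _stage_enrich,
        "survival": _stage_survival,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if stage == "simulate" and config.synthetic is None:
            continue
        t0 = time.perf_counter()
        try:
            produced = stage_fns[stage](config, outdir, state)
        except Exception:
            (outdir / "FAILED").write_text(stage + "\n")
            log.exception("stage %s failed", stage)
            raise
        dt = time.perf_counter() - t0
        log.info("stage %s: %d artifacts in %.1fs", stage, len(produced), dt)
        manifest["stages"][stage] = sorted(produced)
        artifacts.update({k: outdir / k for k in produced})

    for name in ("mutations", "gene_catalog", "clinical", "motif_counts",
                 "genome_fasta", "reference_signatures", "gene_sets",
                 "impact_map"):
        p = state.get(name) or getattr(config, name)
        if p and Path(p).exists():
            manifest["inputs"][name] = _sha256(Path(p))
    for rel in sorted(set().union(*[set(v) for v in
                                    manifest["stages"].values()] or [set()])):
        manifest["outputs"][rel] = _sha256(outdir / rel)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return PipelineResult(outdir=outdir, manifest=manifest, artifacts=artifacts)


# ---------------------------------------------------------------- stages


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    spec = dict(config.synthetic or {})
    spec.setdefault("seed", config.seed)
    cohort = generate_cohort(_synthetic_config(spec))
    paths = cohort.write(outdir / "inputs")
    for name, key in [("mutations", "mutations"), ("catalog", "gene_catalog"),
                      ("clinical", "clinical"), ("motif_counts", "motif_counts"),
                      ("genome", "genome_fasta"), ("gene_sets", "gene_sets"),
                      ("impact_map", "impact_map"),
                      ("reference_signatures", "reference_signatures")]:
        if name in paths:
            state[key] = str(paths[name])
    state["truth"] = cohort.truth
    return [str(p.relative_to(outdir)) for p in paths.values()]


def _input(config: RunConfig, state: dict, name: str) -> str:
    p = state.get(name) or getattr(config, name)
    if p is None or not Path(p).exists():
        raise ConfigError(f"stage requires input {name!r}, not found: {p}")
    return str(p)


def _stage_select_genes(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    records, rej = read_mutations(
        _input(config, state, "mutations"), strict=config.strict)
    catalog = GeneCatalog.from_tsv(_input(config, state, "gene_catalog"))
    coding, drop = filter_coding(records, catalog, strict=config.strict)
    matrix = build_count_matrix(coding)
    table, union, fits = gene_selection.select_candidates(
        matrix, alpha=config.alpha, tail=config.tail)
    state.update(matrix=matrix, records=coding, candidates=union,
                 catalog=catalog)

    matrix.to_tsv(outdir / "cohort_matrix.tsv")
    rej.to_tsv(outdir / "parse_rejections.tsv")
    drop.to_tsv(outdir / "coding_filter_rejections.tsv")
    table.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False,
                 float_format="%.8g")
    pd.Series(union, name="gene_id").to_csv(
        outdir / "candidate_union.tsv", sep="\t", index=False)
    fits_json = {
        ct: {"size": f.size, "prob": f.prob,
             "log_likelihood": f.log_likelihood, "n_obs": f.n_obs}
        for ct, f in fits.items()
    }
    (outdir / "background_fits.json").write_text(
        json.dumps(fits_json, sort_keys=True, indent=1))
    return ["cohort_matrix.tsv", "parse_rejections.tsv",
            "coding_filter_rejections.tsv", "candidate_genes.tsv",
            "candidate_union.tsv", "background_fits.json"]


def _require_matrix(config: RunConfig, outdir: Path, state: dict) -> CohortMatrix:
    if "matrix" not in state:
        state["matrix"] = CohortMatrix.from_tsv(outdir / "cohort_matrix.tsv")
    return state["matrix"]


def _require_candidates(outdir: Path, state: dict) -> list[str]:
    if "candidates" not in state:
        state["candidates"] = list(pd.read_csv(
            outdir / "candidate_union.tsv", sep="\t")["gene_id"])
    return state["candidates"]


def _stage_cluster(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    matrix = _require_matrix(config, outdir, state)
    union = _require_candidates(outdir, state)
    features = clustering.build_features(matrix, union, config.representation)
    tree = clustering.recursive_cluster(features, clustering.ClusterConfig(
        k_max=config.k_max, dominant_fraction=config.dominant_fraction,
        min_node=config.min_node, representation=config.representation,
        seed=config.seed))
    labels = clustering.label_samples(tree)
    state["labels"] = labels
    labels.rename_axis("sample_id").to_csv(outdir / "subtype_labels.tsv", sep="\t")
    (outdir / "subtype_tree.json").write_text(
        json.dumps(tree.to_dict(), sort_keys=True, indent=1))
    return ["subtype_labels.tsv", "subtype_tree.json"]


def _require_labels(outdir: Path, state: dict) -> pd.Series:
    if "labels" not in state:
        df = pd.read_csv(outdir / "subtype_labels.tsv", sep="\t",
                         index_col="sample_id")
        state["labels"] = df["subtype"]
    return state["labels"]


def _stage_characterize(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    import pyfaidx

    matrix = _require_matrix(config, outdir, state)
    labels = _require_labels(outdir, state)
    produced: list[str] = []
    for mm in config.min_mutations_variants:
        load = characterization.mutational_load(matrix, labels, min_mutations=mm)
        name = f"mutational_load_min{mm}.tsv"
        load.to_csv(outdir / name, sep="\t", index_label="gene_id",
                    float_format="%.8g")
        produced.append(name)

    presence = matrix.binary
    gene_tops = characterization.subtype_feature_tests(
        presence, labels, top=config.top)
    state["gene_toplists"] = gene_tops
    for subtype, df in gene_tops.items():
        name = f"top_genes_{subtype}.tsv"
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.8g")
        produced.append(name)
    overlap = characterization.pairwise_overlap(gene_tops)
    overlap.to_csv(outdir / "top_gene_overlap.tsv", sep="\t",
                   index_label="subtype")
    produced.append("top_gene_overlap.tsv")

    if "records" not in state:
        mut_path = state.get("mutations") or config.mutations
        cat_path = state.get("gene_catalog") or config.gene_catalog
        if mut_path and cat_path and Path(mut_path).exists():
            recs, _ = read_mutations(mut_path, strict=config.strict)
            state["records"], _ = filter_coding(
                recs, GeneCatalog.from_tsv(cat_path))
    if "records" in state and (state.get("genome_fasta") or config.genome_fasta):
        fasta = pyfaidx.Fasta(
            _input(config, state, "genome_fasta"), as_raw=True)
        top_genes = sorted({g for df in gene_tops.values()
                            for g in df["feature"]})
        gm = characterization.build_gene_motif_presence(
            state["records"], fasta, genes=top_genes)
        if not gm.empty:
            gm = gm.reindex(matrix.sample_ids, fill_value=0)
            gm_tops = characterization.subtype_feature_tests(
                gm, labels, top=config.top)
            for subtype, df in gm_tops.items():
                name = f"top_gene_motifs_{subtype}.tsv"
                df.to_csv(outdir / name, sep="\t", index=False,
                          float_format="%.8g")
                produced.append(name)
            gm_overlap = characterization.pairwise_overlap(gm_tops)
            gm_overlap.to_csv(outdir / "top_gene_motif_overlap.tsv", sep="\t",
                              index_label="subtype")
            produced.append("top_gene_motif_overlap.tsv")

    if "records" in state:
        impact_path = state.get("impact_map") or config.impact_map
        imap = (characterization.load_impact_map(impact_path)
                if impact_path else {})
        cons = characterization.consequence_frequencies(
            state["records"], labels, imap)
        cons.to_csv(outdir / "consequence_frequencies.tsv", sep="\t",
                    float_format="%.8g")
        produced.append("consequence_frequencies.tsv")
    return produced


def _stage_signatures(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    labels = _require_labels(outdir, state)
    motif = pd.read_csv(_input(config, state, "motif_counts"), sep="\t",
                        index_col="sample_id")
    produced: list[str] = []
    all_sets: list[sigmod.SignatureSet] = []
    for i, (subtype, idx) in enumerate(sorted(labels.groupby(labels).groups.items())):
        sub = motif.reindex(list(idx)).dropna().astype(int)
        if len(sub) < config.n_range[0] + 2 or sub.to_numpy().sum() == 0:
            continue
        sset = sigmod.extract_signatures(
            sub, subtype, n_range=config.n_range, seed=config.seed + i,
            restarts=config.nmf_restarts, n_boot=config.nmf_bootstrap)
        all_sets.append(sset)
        for frame, tag in [(sset.W, "signatures"), (sset.H, "exposures"),
                           (sset.metrics, "metrics")]:
            name = f"{tag}_{subtype}.tsv"
            frame.to_csv(outdir / name, sep="\t", float_format="%.8g")
            produced.append(name)
    state["signature_sets"] = all_sets

    ref_path = state.get("reference_signatures") or config.reference_signatures
    if ref_path and all_sets:
        ref = sigmod.load_reference_signatures(ref_path)
        W_all = pd.concat([s.W for s in all_sets], axis=1)
        sim = sigmod.angular_similarity(W_all, ref)
        sim.to_csv(outdir / "signature_similarity.tsv", sep="\t",
                   float_format="%.8g")
        produced.append("signature_similarity.tsv")
        cross = sigmod.angular_similarity(W_all, W_all / W_all.sum(axis=0))
        cross.to_csv(outdir / "signature_cross_similarity.tsv", sep="\t",
                     float_format="%.8g")
        produced.append("signature_cross_similarity.tsv")
    return produced


def _stage_enrich(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    gmt_path = state.get("gene_sets") or config.gene_sets
    if gmt_path is None:
        return []
    collection = enrichment.read_gmt(gmt_path)
    catalog: GeneCatalog | None = state.get("catalog")
    if catalog is None:
        catalog = GeneCatalog.from_tsv(_input(config, state, "gene_catalog"))
    universe = catalog.coding_genes
    gene_tops = state.get("gene_toplists")
    if gene_tops is None:
        matrix = _require_matrix(config, outdir, state)
        labels = _require_labels(outdir, state)
        gene_tops = characterization.subtype_feature_tests(
            matrix.binary, labels, top=config.top)
    produced = []
    for subtype, df in sorted(gene_tops.items()):
        query = [g for g in df["feature"] if g in set(universe)]
        res = enrichment.enrich(query, collection, universe,
                                fdr_threshold=config.enrichment_fdr)
        name = f"enrichment_{subtype}.tsv"
        res.to_csv(outdir / name, sep="\t", index=False, float_format="%.8g")
        produced.append(name)
    return produced


def _stage_survival(config: RunConfig, outdir: Path, state: dict) -> list[str]:
    clin_path = state.get("clinical") or config.clinical
    if clin_path is None:
        return []
    clinical = pd.read_csv(clin_path, sep="\t")
    labels = _require_labels(outdir, state)
    if "sample_id" in clinical.columns:
        sample_to_donor = clinical.set_index("sample_id")["donor_id"]
    else:
        sample_to_donor = pd.Series(labels.index, index=labels.index)
    donor_subtype, excluded = survmod.filter_consistent_donors(
        sample_to_donor.reindex(labels.index), labels)
    curves, chi, dof, p, summary = survmod.subtype_survival(
        clinical, donor_subtype)
    produced = []
    km_rows = []
    for subtype, curve in sorted(curves.items()):
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
            km_rows.append({"subtype": subtype, "time_days": t,
                            "survival": s, "at_risk": int(r)})
    pd.DataFrame(km_rows).to_csv(outdir / "km_curves.tsv", sep="\t",
                                 index=False, float_format="%.8g")
    produced.append("km_curves.tsv")
    summary.to_csv(outdir / "survival_summary.tsv", sep="\t", index=False,
                   float_format="%.8g")
    produced.append("survival_summary.tsv")
    (outdir / "logrank.json").write_text(json.dumps({
        "chi_square": chi, "df": dof, "p_value": p,
        "excluded_donors": excluded,
    }, sort_keys=True, indent=1))
    produced.append("logrank.json")
    state["logrank"] = (chi, dof, p)
    for attr in ("gender", "region"):
        if attr in clinical.columns:
            comp = survmod.composition_summary(clinical, donor_subtype, attr)
            name = f"composition_{attr}.tsv"
            comp.to_csv(outdir / name, sep="\t", float_format="%.8g")
            produced.append(name)
    return produced
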