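"""Synthetic ICGC-like cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* per-gene mutated-sample counts within each cancer type follow a negative
  binomial (implemented as its gamma-Poisson mixture: each gene in each
  cancer type draws a rate ``lambda_g ~ Gamma(r, q/p)`` and every sample is
  mutated with probability ``lambda_g / n_type``, so that the mutated-sample
  count is NB(r, p) up to a vanishing binomial correction);
* a planted subtype structure: samples of subtype j have their per-sample
  mutation probability multiplied by ``elevation_factor`` (capped at 1) in
  that subtype's elevated genes;
* optional within-gene multiplicity (geometric extra mutations) so analyses
  thresholded at >= 3 mutations per gene are exercisable;
* per-sample 96-channel motif counts drawn multinomially from an
  exposure-weighted mixture of planted signatures;
* exponential survival with subtype-specific hazards and independent
  exponential censoring calibrated to the requested censoring rate.

Everything is driven by a single master seed; identical configs and seeds
produce byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_profiles import BASES, MOTIF_CLASSES

_BASE_LIST = sorted(BASES)

CONSEQUENCE_VOCAB = (
    "missense_variant",
    "synonymous_variant",
    "stop_gained",
    "intron_variant",
    "",
)
CONSEQUENCE_PROBS = (0.50, 0.25, 0.05, 0.15, 0.05)

#: Ensembl-style impact classes for the synthetic consequence vocabulary.
IMPACT_MAP = {
    "missense_variant": "MODERATE",
    "synonymous_variant": "LOW",
    "stop_gained": "HIGH",
    "intron_variant": "MODIFIER",
}

GENE_WINDOW = 40  # bp of toy contig allotted per gene


@dataclass(frozen=True)
class SubtypeSpec:
    """One planted subtype: mixture weight, elevated gene indices, factor."""

    weight: float
    elevated_genes: tuple[int, ...]
    elevation_factor: float = 10.0


def default_subtype_spec(n_subtypes: int = 4, genes_per_subtype: int = 10,
                         elevation_factor: float = 10.0) -> tuple[SubtypeSpec, ...]:
    """Equal-weight subtypes with disjoint elevated gene blocks."""
    w = 1.0 / n_subtypes
    return tuple(
        SubtypeSpec(
            weight=w,
            elevated_genes=tuple(
                range(j * genes_per_subtype, (j + 1) * genes_per_subtype)),
            elevation_factor=elevation_factor,
        )
        for j in range(n_subtypes)
    )


def separated_signatures(n: int, seed: int = 0, concentration: float = 0.05,
                         max_cosine: float = 0.3) -> np.ndarray:
    """Draw n sparse, well-separated 96-channel signatures (rows sum to 1).

    A small Dirichlet concentration puts each signature's mass on a few
    channels; draws are rejected until every pairwise cosine similarity is
    at most ``max_cosine``.
    """
    rng = np.random.default_rng(seed)
    sigs = [rng.dirichlet(np.full(96, concentration))]
    tries = 0
    while len(sigs) < n:
        cand = rng.dirichlet(np.full(96, concentration))
        norm_c = np.linalg.norm(cand)
        ok = all(
            np.dot(cand, s) / (norm_c * np.linalg.norm(s)) <= max_cosine
            for s in sigs)
        if ok:
            sigs.append(cand)
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not draw sufficiently separated signatures")
    out = np.array(sigs)
    return out / out.sum(axis=1, keepdims=True)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the package's standard experimental configuration: 500
    samples over 2 cancer types and 5,000 genes; per-gene mutated-sample
    counts NB(size=40, p=4/7) within a cancer type (mean 30, i.e. a typical
    gene is mutated in ~12% of a 250-sample cancer type); four equal planted
    subtypes each elevating a disjoint block of 10 genes tenfold; three
    planted signatures; exponential survival with subtype medians of roughly
    8/6/4/2 years and ~20% censoring.
    """

    n_samples: int = 500
    n_genes: int = 5000
    n_cancer_types: int = 2
    nb_size: float = 40.0
    nb_prob: float = 40.0 / 70.0
    subtype_spec: tuple[SubtypeSpec, ...] = field(default_factory=default_subtype_spec)
    signature_spec: np.ndarray | None = None  # (k, 96); default: 3 separated
    exposure_dirichlet: tuple[float, ...] | None = None  # default: 0.5 each
    motif_mutations_mean: float = 600.0
    multiplicity_p: float = 0.7  # extra within-gene mutations ~ Geom; mean (1-p)/p
    survival_hazards: tuple[float, ...] | None = None  # per-day, per subtype
    censor_rate: float = 0.2
    n_noncoding_genes: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(s.weight for s in self.subtype_spec)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"subtype weights must sum to 1, got {w}")
        if not 0 < self.nb_prob < 1:
            raise ValueError("nb_prob must lie in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        top = max((max(s.elevated_genes, default=-1)
                   for s in self.subtype_spec), default=-1)
        if top >= self.n_genes:
            raise ValueError(
                f"elevated gene index {top} out of range for "
                f"{self.n_genes} genes")
        if self.signature_spec is None:
            object.__setattr__(
                self, "signature_spec", separated_signatures(3, seed=self.seed))
        sigs = np.asarray(self.signature_spec, dtype=float)
        if sigs.ndim != 2 or sigs.shape[1] != 96 or (sigs < 0).any():
            raise ValueError("signature_spec must be a nonnegative (k, 96) array")
        if not np.allclose(sigs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each planted signature must sum to 1")
        if self.exposure_dirichlet is None:
            object.__setattr__(
                self, "exposure_dirichlet", (0.5,) * sigs.shape[0])
        if self.survival_hazards is None:
            medians_years = (8.0, 6.0, 4.0, 2.0)
            hz = tuple(
                math.log(2.0) / (medians_years[j % len(medians_years)] * 365.25)
                for j in range(len(self.subtype_spec)))
            object.__setattr__(self, "survival_hazards", hz)
        if len(self.survival_hazards) != len(self.subtype_spec):
            raise ValueError("need one survival hazard per subtype")

    @property
    def n_signatures(self) -> int:
        return np.asarray(self.signature_spec).shape[0]


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated cohort."""

    subtype_of_sample: pd.Series  # sample_id -> "T1".."Tk"
    cancer_type_of_sample: pd.Series
    elevated_genes: dict[str, list[str]]  # subtype -> gene ids
    elevation_factor: dict[str, float]
    signatures: pd.DataFrame  # planted signatures x 96 channels
    exposures: pd.DataFrame  # sample x planted signature weights
    hazard_per_day: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subtype_of_sample": self.subtype_of_sample.to_dict(),
            "cancer_type_of_sample": self.cancer_type_of_sample.to_dict(),
            "elevated_genes": self.elevated_genes,
            "elevation_factor": self.elevation_factor,
            "signatures": self.signatures.round(10).values.tolist(),
            "signature_names": list(self.signatures.index),
            "exposures": self.exposures.round(10).values.tolist(),
            "exposure_samples": list(self.exposures.index),
            "hazard_per_day": self.hazard_per_day,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_count_matrix(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Draw the sample x gene mutation-count matrix plus labels.

    Returns (counts, cancer_type_of_sample, subtype_of_sample). Counts carry
    within-gene multiplicity; the per-gene mutated-sample count within a
    cancer type is NB(nb_size, nb_prob) before subtype elevation.
    """
    n, g = config.n_samples, config.n_genes
    samples = _sample_ids(n)
    genes = _gene_ids(g)
    ctype = np.array([f"CT{(i % config.n_cancer_types) + 1}" for i in range(n)])
    weights = np.array([s.weight for s in config.subtype_spec])
    subtype_idx = rng.choice(len(weights), size=n, p=weights)
    # regenerate (rare) empty subtypes so every planted subtype is populated
    for _ in range(100):
        if len(np.unique(subtype_idx)) == len(weights):
            break
        subtype_idx = rng.choice(len(weights), size=n, p=weights)

    elev = np.ones((len(weights), g))
    for j, spec in enumerate(config.subtype_spec):
        elev[j, list(spec.elevated_genes)] = spec.elevation_factor

    counts = np.zeros((n, g), dtype=np.int64)
    q = 1.0 - config.nb_prob
    scale = q / config.nb_prob  # gamma scale of the NB mixing distribution
    for t in sorted(set(ctype)):
        rows = np.flatnonzero(ctype == t)
        n_t = len(rows)
        lam = rng.gamma(shape=config.nb_size, scale=scale, size=g)
        base = lam / max(n_t, 1)
        prob = np.minimum(1.0, base[None, :] * elev[subtype_idx[rows], :])
        mutated = rng.random((n_t, g)) < prob
        extra = rng.geometric(config.multiplicity_p, size=mutated.shape) - 1
        counts[rows, :] = mutated * (1 + extra)

    counts_df = pd.DataFrame(counts, index=samples, columns=genes)
    return (
        counts_df,
        pd.Series(ctype, index=samples, name="cancer_type"),
        pd.Series([f"T{j + 1}" for j in subtype_idx], index=samples, name="subtype"),
    )


def generate_motif_table(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample 96-channel counts from the planted signature mixture.

    Returns (motif_counts, exposures). Each sample draws an exposure vector
    from Dirichlet(exposure_dirichlet) and a total mutation count from
    Poisson(motif_mutations_mean); channel counts are multinomial from the
    exposure-weighted signature mixture, so expected channel frequencies
    equal the mixture.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sigs = np.asarray(config.signature_spec, dtype=float)
    n = config.n_samples
    samples = _sample_ids(n)
    exposures = rng.dirichlet(np.asarray(config.exposure_dirichlet), size=n)
    totals = rng.poisson(config.motif_mutations_mean, size=n)
    probs = exposures @ sigs  # (n, 96)
    counts = np.zeros((n, 96), dtype=np.int64)
    for i in range(n):
        if totals[i] > 0:
            counts[i] = rng.multinomial(totals[i], probs[i])
    sig_names = [f"SYN{j + 1}" for j in range(sigs.shape[0])]
    return (
        pd.DataFrame(counts, index=samples, columns=list(MOTIF_CLASSES)),
        pd.DataFrame(exposures, index=samples, columns=sig_names),
    )


def _simulate_clinical(
    config: SyntheticConfig,
    subtype_idx: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = config.n_samples
    hz = np.asarray(config.survival_hazards)[subtype_idx]
    t_event = rng.exponential(1.0 / hz)
    if config.censor_rate > 0:
        c_rate = config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / (hz * c_rate))
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    gender = rng.choice(["female", "male"], size=n)
    region = rng.choice(["US", "KR", "SA"], size=n, p=[0.6, 0.25, 0.15])
    return pd.DataFrame({
        "donor_id": [f"D{i:05d}" for i in range(n)],
        "sample_id": _sample_ids(n),
        "survival_days": np.round(time, 3),
        "event": event,
        "gender": gender,
        "region": region,
    })


def _toy_genome(n_genes: int, rng: np.random.Generator) -> str:
    length = n_genes * GENE_WINDOW + 2
    return "".join(np.array(_BASE_LIST)[rng.integers(0, 4, size=length)])


def _expand_records(
    counts: pd.DataFrame,
    ctype: pd.Series,
    genome: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Turn the count matrix into concrete SNV rows on the toy contig."""
    usable = GENE_WINDOW - 3  # loci per gene window, >= 2 bases from edges
    mat = np.minimum(counts.to_numpy(), usable)  # distinct loci per (sample, gene)
    s_pos, g_pos = np.nonzero(mat)
    reps = mat[s_pos, g_pos]
    s_all = np.repeat(s_pos, reps)
    g_all = np.repeat(g_pos, reps)
    m = len(s_all)
    # distinct loci per (sample, gene): random anchor plus occurrence index
    anchor = np.repeat(rng.integers(0, usable, size=len(reps)), reps)
    occ = np.arange(m) - np.repeat(np.cumsum(reps) - reps, reps)
    offset = (anchor + occ) % usable + 2
    pos = g_all * GENE_WINDOW + offset + 1  # 1-based
    contig = np.frombuffer(genome.encode(), dtype="S1").astype("U1")
    ref = contig[pos - 1]
    base_idx = np.searchsorted(_BASE_LIST, ref)
    alt_idx = (base_idx + rng.integers(1, 4, size=m)) % 4
    alt = np.array(_BASE_LIST)[alt_idx]
    samples = np.asarray(counts.index)
    genes = np.asarray(counts.columns)
    cons = rng.choice(CONSEQUENCE_VOCAB, size=m, p=CONSEQUENCE_PROBS)
    frame = pd.DataFrame({
        "icgc_sample_id": samples[s_all],
        "icgc_donor_id": np.char.replace(samples[s_all].astype(str), "S", "D"),
        "chromosome": "1",
        "chromosome_start": pos,
        "reference_genome_allele": ref,
        "mutated_to_allele": alt,
        "gene_affected": genes[g_all],
        "consequence_type": cons,
        "project_code": ctype.reindex(samples[s_all]).to_numpy(),
    })
    return frame.sort_values(
        ["icgc_sample_id", "gene_affected", "chromosome_start"],
        kind="mergesort").reset_index(drop=True)


@dataclass
class SyntheticCohort:
    """A generated cohort: tables, toy genome, catalogs and ground truth."""

    config: SyntheticConfig
    mutations: pd.DataFrame | None  # ICGC-dialect rows (None if not expanded)
    counts: pd.DataFrame
    cancer_type_of_sample: pd.Series
    clinical: pd.DataFrame
    motif_counts: pd.DataFrame
    genome: str | None
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact as plain text; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        if self.mutations is not None:
            paths["mutations"] = outdir / "mutations.tsv"
            self.mutations.to_csv(paths["mutations"], sep="\t", index=False)
        if self.genome is not None:
            paths["genome"] = outdir / "genome.fa"
            with open(paths["genome"], "w") as fh:
                fh.write(">1\n")
                for i in range(0, len(self.genome), 70):
                    fh.write(self.genome[i:i + 70] + "\n")

        paths["clinical"] = outdir / "clinical.tsv"
        self.clinical.to_csv(paths["clinical"], sep="\t", index=False)

        paths["motif_counts"] = outdir / "motif_counts.tsv"
        self.motif_counts.to_csv(paths["motif_counts"], sep="\t",
                                 index_label="sample_id")

        paths["catalog"] = outdir / "gene_catalog.tsv"
        rows = [(g, g, 1) for g in self.counts.columns]
        rows += [(f"NC{i:03d}", f"NC{i:03d}", 0)
                 for i in range(self.config.n_noncoding_genes)]
        pd.DataFrame(rows, columns=["gene_id", "symbol", "is_coding"]).to_csv(
            paths["catalog"], sep="\t", index=False)

        paths["gene_sets"] = outdir / "gene_sets.gmt"
        self._write_gmt(paths["gene_sets"])

        paths["impact_map"] = outdir / "impact_map.tsv"
        pd.DataFrame(sorted(IMPACT_MAP.items()),
                     columns=["consequence", "impact"]).to_csv(
            paths["impact_map"], sep="\t", index=False)

        paths["reference_signatures"] = outdir / "reference_signatures.tsv"
        ref = self.truth.signatures.T.copy()  # 96 x k, COSMIC-like layout
        ref.insert(0, "Type", list(MOTIF_CLASSES))
        ref.to_csv(paths["reference_signatures"], sep="\t", index=False,
                   float_format="%.10g")

        paths["truth"] = outdir / "truth.json"
        self.truth.to_json(paths["truth"])
        return paths

    def _write_gmt(self, path: Path) -> None:
        """Planted elevated-gene sets plus seeded random decoy sets."""
        rng = np.random.default_rng(self.config.seed + 7)
        genes = list(self.counts.columns)
        lines = []
        for name, members in sorted(self.truth.elevated_genes.items()):
            lines.append(f"PLANTED_{name}\tplanted elevated genes\t"
                         + "\t".join(members))
        for i in range(20):
            members = sorted(rng.choice(genes, size=25, replace=False))
            lines.append(f"DECOY_{i:02d}\trandom gene set\t" + "\t".join(members))
        Path(path).write_text("\n".join(lines) + "\n")


def generate_cohort(
    config: SyntheticConfig, expand_records: bool = True
) -> SyntheticCohort:
    """Generate a full synthetic cohort from one master seed.

    With ``expand_records=False`` only the count matrix, clinical, motif and
    truth tables are built (fast path for large experiments); the ICGC-style
    mutation rows and toy genome are skipped.
    """
    master = np.random.default_rng(config.seed)
    counts, ctype, subtype = simulate_count_matrix(config, master)
    subtype_idx = subtype.str.lstrip("T").astype(int).to_numpy() - 1
    clinical = _simulate_clinical(config, subtype_idx, master)
    motif_counts, exposures = generate_motif_table(config, master)

    genes = list(counts.columns)
    sig_names = [f"SYN{j + 1}" for j in range(config.n_signatures)]
    truth = SyntheticTruth(
        subtype_of_sample=subtype,
        cancer_type_of_sample=ctype,
        elevated_genes={
            f"T{j + 1}": [genes[i] for i in spec.elevated_genes]
            for j, spec in enumerate(config.subtype_spec)
        },
        elevation_factor={
            f"T{j + 1}": spec.elevation_factor
            for j, spec in enumerate(config.subtype_spec)
        },
        signatures=pd.DataFrame(np.asarray(config.signature_spec),
                                index=sig_names, columns=list(MOTIF_CLASSES)),
        exposures=exposures,
        hazard_per_day={
            f"T{j + 1}": h for j, h in enumerate(config.survival_hazards)
        },
    )

    genome = mutations = None
    if expand_records:
        genome = _toy_genome(config.n_genes, master)
        mutations = _expand_records(counts, ctype, genome, master)
        mutations = _add_noncoding_records(mutations, config, ctype, master)

    return SyntheticCohort(
        config=config,
        mutations=mutations,
        counts=counts,
        cancer_type_of_sample=ctype,
        clinical=clinical,
        motif_counts=motif_counts,
        genome=genome,
        truth=truth,
    )


def _add_noncoding_records(
    mutations: pd.DataFrame,
    config: SyntheticConfig,
    ctype: pd.Series,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sprinkle a few non-coding-gene rows so coding filters are exercised."""
    if config.n_noncoding_genes == 0:
        return mutations
    n_extra = rng.poisson(0.05 * config.n_samples)
    if n_extra == 0:
        return mutations
    samples = np.asarray(ctype.index)
    pick = rng.integers(0, len(samples), size=n_extra)
    nc = rng.integers(0, config.n_noncoding_genes, size=n_extra)
    ref = rng.choice(_BASE_LIST, size=n_extra)
    alt_idx = (np.searchsorted(_BASE_LIST, ref) + rng.integers(1, 4, n_extra)) % 4
    extra = pd.DataFrame({
        "icgc_sample_id": samples[pick],
        "icgc_donor_id": np.char.replace(samples[pick].astype(str), "S", "D"),
        "chromosome": "2",
        "chromosome_start": rng.integers(100, 10_000, size=n_extra),
        "reference_genome_allele": ref,
        "mutated_to_allele": np.array(_BASE_LIST)[alt_idx],
        "gene_affected": [f"NC{i:03d}" for i in nc],
        "consequence_type": "intergenic_region",
        "project_code": ctype.reindex(samples[pick]).to_numpy(),
    })
    out = pd.concat([mutations, extra], ignore_index=True)
    return out.sort_values(
        ["icgc_sample_id", "gene_affected", "chromosome_start"],
        kind="mergesort").reset_index(drop=True)
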