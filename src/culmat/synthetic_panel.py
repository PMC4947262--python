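"""Seeded synthetic diversity panels with planted, fully recorded truth.

The generator emulates the statistical structure an Associative
Transcriptomics analysis of an inbred wheat panel assumes, so that every
downstream stage (marker scoring, structure estimation, mixed-model
association, validation) can be exercised end to end without external data.

Structure model
---------------
Genotypes follow the Balding–Nichols construction: an ancestral allele
frequency ``p0_j ~ Uniform(0.05, 0.95)`` per site, population frequencies

    p_kj ~ Beta(p0_j (1-F)/F, (1-p0_j)(1-F)/F),   F = fst,

admixture proportions ``q_i ~ Dirichlet(alpha * 1_K)`` per accession, and —
the lines being fully homozygous inbreds — a single allele draw doubled:
``g_ij = 2 * Bernoulli(sum_k q_ik p_kj)``.  Dosage is therefore in {0, 2}.

On top of the genotypes the module simulates allele read depths (Poisson
total depth, uniform sequencing-error misreads), expression read counts
(log-normal baselines, optional cis effects wired to markers, Poisson
counting noise), replicate phenotype records (causal SNP/GEM fixed effects,
a kinship-structured polygenic term scaled by ``h2_polygenic``, year
offsets, replicate noise), and three-point-bend specimens whose recorded
forces and cross-section areas invert exactly to the latent moduli.

Everything random is driven by one seed; the planted truth (frequencies,
ancestry, causal assignments, latent traits) is serialised alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .marker_scoring import ALLELES, AlleleDepthTensor, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GeometryConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_read_depths",
    "simulate_expression",
    "simulate_phenotypes",
    "simulate_specimens",
    "simulate_panel",
    "default_marker_map",
]

#: Wheat pseudomolecule labels (7 homoeologous groups x 3 genomes).
WHEAT_CHROMOSOMES = tuple(f"{g}{s}" for g in range(1, 8) for s in "ABD")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class GeometryConfig:
    """Bend-test specimen geometry sampling.

    The span matches the assay's 2.5 cm support separation; the probe loads
    centrally so the half-span is L/2.  Outer diameters and hollow
    fractions are drawn uniformly within ranges typical of dried wheat
    second internodes.
    """

    span_L: float = 25.0  # mm
    d2_range: tuple[float, float] = (2.0, 4.0)  # mm, outer diameter
    hollow_frac_range: tuple[float, float] = (0.0, 0.7)  # D1a / D2
    breakage_p: float = 0.5  # field stem-failure probability
    breakage_plants: int = 6


@dataclass
class SimulationConfig:
    """All knobs of the synthetic panel, with study-scale defaults.

    Defaults mirror the analysed panel where its design is known (100
    inbred accessions, two harvest years with 10 and 5 replicate plants,
    mean read coverage near 6x) and desk-scale but structured values
    elsewhere (K_true=3 ancestral groups at fst=0.3, thousands of markers).
    Causal effects are in trait units per unit of the standardised
    predictor (allele dosage/2 for SNPs, log2 expression for GEMs).
    """

    seed: int = 0
    n_accessions: int = 100
    n_populations: int = 3  # K_true
    fst: float = 0.3
    dirichlet_alpha: float = 0.2
    n_snps: int = 2000
    n_unigenes: int = 1000
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    causal_gems: list[tuple[int, float]] = field(default_factory=list)
    cis_links: list[tuple[int, int, float]] = field(default_factory=list)
    h2_polygenic: float = 0.5
    sigma_e: float = 1.0
    year_effects: dict[int, float] = field(
        default_factory=lambda: {2011: 0.0, 2012: 0.5}
    )
    reps_per_year: dict[int, int] = field(
        default_factory=lambda: {2011: 10, 2012: 5}
    )
    depth_mean: float = 6.0
    seq_error: float = 0.01
    expr_baseline_mean: float = 3.0  # log2 RPKM-scale units
    expr_baseline_sd: float = 2.0
    expr_sigma: float = 0.5  # accession-level log2 noise
    poisson_counts: bool = True
    mor_baseline: float = 4.0  # N mm^-2
    moe_baseline: float = 800.0  # N mm^-2
    moe_per_mor: float = 150.0
    moe_extra_sd: float = 80.0
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def validate(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie strictly in (0, 1)")
        for name in ("n_accessions", "n_populations", "n_snps", "n_unigenes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must be in [0, 1)")
        if self.seq_error >= 0.5:
            raise ValueError("seq_error must be below 0.5")
        if self.seq_error < 0:
            raise ValueError("seq_error must be non-negative")
        for idx, _ in self.causal_snps:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"causal SNP index {idx} out of range")
        for idx, _ in self.causal_gems:
            if not 0 <= idx < self.n_unigenes:
                raise ValueError(f"causal GEM index {idx} out of range")
        for u, m, _ in self.cis_links:
            if not (0 <= u < self.n_unigenes and 0 <= m < self.n_snps):
                raise ValueError(f"cis link ({u}, {m}) out of range")


@dataclass
class TruthRecord:
    """Planted ground truth of one simulated panel, JSON-serialisable."""

    ancestral_freqs: np.ndarray  # (m,)
    population_freqs: np.ndarray  # (K, m)
    admixture_q: np.ndarray  # (n, K)
    genotypes: pd.DataFrame | None = None
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    causal_gems: list[tuple[int, float]] = field(default_factory=list)
    cis_links: list[tuple[int, int, float]] = field(default_factory=list)
    latent_traits: dict[str, pd.Series] = field(default_factory=dict)

    def population_labels(self) -> np.ndarray:
        """Hard assignment: each accession's majority-ancestry population."""
        return np.argmax(self.admixture_q, axis=1)

    def to_json(self, path) -> None:
        payload = {
            "ancestral_freqs": self.ancestral_freqs.tolist(),
            "population_freqs": self.population_freqs.tolist(),
            "admixture_q": self.admixture_q.tolist(),
            "causal_snps": [list(t) for t in self.causal_snps],
            "causal_gems": [list(t) for t in self.causal_gems],
            "cis_links": [list(t) for t in self.cis_links],
            "latent_traits": {
                k: {"index": list(v.index), "values": v.tolist()}
                for k, v in self.latent_traits.items()
            },
        }
        if self.genotypes is not None:
            payload["genotypes"] = {
                "index": list(self.genotypes.index),
                "columns": list(self.genotypes.columns),
                "values": self.genotypes.to_numpy().tolist(),
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        geno = None
        if "genotypes" in d:
            g = d["genotypes"]
            geno = pd.DataFrame(g["values"], index=g["index"], columns=g["columns"])
            geno.index.name = "accession"
        return cls(
            ancestral_freqs=np.asarray(d["ancestral_freqs"]),
            population_freqs=np.asarray(d["population_freqs"]),
            admixture_q=np.asarray(d["admixture_q"]),
            genotypes=geno,
            causal_snps=[tuple(t) for t in d["causal_snps"]],
            causal_gems=[tuple(t) for t in d["causal_gems"]],
            cis_links=[tuple(t) for t in d["cis_links"]],
            latent_traits={
                k: pd.Series(v["values"], index=v["index"])
                for k, v in d["latent_traits"].items()
            },
        )


def default_marker_map(
    unigenes: Sequence[str], seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Assign unigenes to wheat pseudomolecules with ordinal positions.

    Chromosome membership is drawn at random; within a chromosome the
    retained unigene order defines the ordinal coordinate, mimicking a
    synteny-derived pseudomolecule map.
    """
    rng = _rng(seed)
    chroms = rng.choice(WHEAT_CHROMOSOMES, size=len(unigenes))
    map_df = pd.DataFrame({"unigene": list(unigenes), "chromosome": chroms})
    map_df["position"] = map_df.groupby("chromosome").cumcount() + 1
    return map_df.set_index("unigene")


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Balding–Nichols structured inbred genotypes plus the truth record."""
    config.validate()
    rng = _rng(config.seed if rng is None else rng)
    n, m, K, F = (
        config.n_accessions,
        config.n_snps,
        config.n_populations,
        config.fst,
    )
    p0 = rng.uniform(0.05, 0.95, size=m)
    scale = (1.0 - F) / F
    pkj = rng.beta(p0 * scale, (1.0 - p0) * scale, size=(K, m))
    q = rng.dirichlet(np.full(K, config.dirichlet_alpha), size=n)
    theta = q @ pkj
    g = 2.0 * (rng.random((n, m)) < theta)

    accessions = pd.Index([f"ACC{i:03d}" for i in range(n)], name="accession")
    unigene_ids = [f"UG{j:05d}" for j in range(config.n_unigenes)]
    site_unigene = rng.integers(0, config.n_unigenes, size=m)
    offsets = rng.integers(1, 2000, size=m)
    marker_ids = pd.Index(
        [f"{unigene_ids[u]}:{o}_{j}" for j, (u, o) in enumerate(zip(site_unigene, offsets))]
    )
    allele_pairs = np.array(
        [rng.choice(len(ALLELES), size=2, replace=False) for _ in range(m)]
    )
    calls = pd.DataFrame(g, index=accessions, columns=marker_ids)
    info = pd.DataFrame(
        {
            "unigene": [unigene_ids[u] for u in site_unigene],
            "allele_minor": [ALLELES[i] for i in allele_pairs[:, 0]],
            "allele_major": [ALLELES[i] for i in allele_pairs[:, 1]],
        },
        index=marker_ids,
    )
    gm = GenotypeMatrix(calls, info)
    gm.info["maf"] = gm.maf()
    truth = TruthRecord(
        ancestral_freqs=p0,
        population_freqs=pkj,
        admixture_q=q,
        genotypes=calls,
        causal_snps=list(config.causal_snps),
        causal_gems=list(config.causal_gems),
        cis_links=list(config.cis_links),
    )
    return gm, truth


def simulate_read_depths(
    genotypes: GenotypeMatrix,
    depth_mean: float,
    seq_error: float,
    seed: int | np.random.Generator = 0,
) -> AlleleDepthTensor:
    """Poisson-depth allele read counts with uniform misread errors.

    Each accession x site draws a Poisson total depth; every read reports
    the true allele with probability 1 - seq_error, otherwise one of the
    three other bases uniformly.  Missing genotypes produce zero depth.
    """
    if seq_error >= 0.5:
        raise ValueError("seq_error must be below 0.5")
    rng = _rng(seed)
    calls = genotypes.calls.to_numpy(float)
    n, m = calls.shape
    info = genotypes.info
    minor_idx = info["allele_minor"].map({a: i for i, a in enumerate(ALLELES)}).to_numpy()
    major_idx = info["allele_major"].map({a: i for i, a in enumerate(ALLELES)}).to_numpy()
    true_idx = np.where(calls == 2.0, minor_idx[None, :], major_idx[None, :])

    total = rng.poisson(depth_mean, size=(n, m))
    total = np.where(np.isfinite(calls), total, 0)
    errors = rng.binomial(total, seq_error)
    correct = total - errors
    counts = np.zeros((n, m, len(ALLELES)), dtype=np.int64)
    ii, jj = np.indices((n, m))
    np.add.at(counts, (ii, jj, true_idx), correct)
    # spread error reads over the three non-true bases
    if errors.any():
        others = np.argsort(
            np.eye(len(ALLELES))[true_idx], axis=-1
        )[..., : len(ALLELES) - 1]  # indices of the 3 non-true alleles
        split = rng.multinomial(errors.ravel(), np.full(3, 1 / 3)).reshape(n, m, 3)
        for k in range(3):
            np.add.at(counts, (ii, jj, others[..., k]), split[..., k])
    site_info = info[["unigene"]].copy() if "unigene" in info.columns else None
    return AlleleDepthTensor(
        counts, genotypes.accessions, genotypes.markers, site_info
    )


def simulate_expression(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Unigene read counts with optional cis-genetic control.

    log2 expression = baseline_j + cis_effect * (g/2) + Normal(0, expr_sigma);
    counts are Poisson around expression x (length/1000) x library factor
    (or exact expectations when ``poisson_counts`` is off, for noise-free
    checks).  Returns (counts, unigene lengths, total aligned reads).
    """
    rng = _rng(seed)
    n = len(genotypes.accessions)
    J = config.n_unigenes
    unigene_ids = pd.Index([f"UG{j:05d}" for j in range(J)], name="unigene")

    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=J)
    log2_expr = np.tile(baseline, (n, 1))
    if config.expr_sigma > 0:
        log2_expr = log2_expr + rng.normal(0.0, config.expr_sigma, size=(n, J))
    g = genotypes.calls.to_numpy(float)
    for u, mkr, eff in config.cis_links:
        dosage = np.nan_to_num(g[:, mkr], nan=0.0) / 2.0
        log2_expr[:, u] = log2_expr[:, u] + eff * dosage

    expr = np.exp2(log2_expr)
    lengths = pd.Series(
        rng.integers(300, 3000, size=J).astype(float), index=unigene_ids, name="length"
    )
    libfactor = 30.0 * rng.lognormal(0.0, 0.2, size=n)
    lam = expr * (lengths.to_numpy() / 1000.0)[None, :] * libfactor[:, None]
    counts = rng.poisson(lam).astype(float) if config.poisson_counts else lam
    counts = pd.DataFrame(counts, index=genotypes.accessions, columns=unigene_ids)
    totals = counts.sum(axis=1)
    totals.name = "total_reads"
    return counts, lengths, totals


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    log2_expression: pd.DataFrame | None,
    kinship: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    baseline: float = 0.0,
    trait: str = "trait",
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate-level trait records from planted effects + polygenic noise.

    Accession value = baseline + sum(causal SNP effect x dosage/2)
    + sum(causal GEM effect x centred log2 expression) + polygenic draw
    ~ N(0, sigma_g^2 K) with sigma_g^2 = h2/(1-h2) * sigma_e^2, then per
    replicate a year offset and Normal(0, sigma_e^2) noise.  Returns the
    long table and the latent per-accession values.
    """
    rng = _rng(seed)
    acc = genotypes.accessions
    n = len(acc)
    Kmat = kinship.reindex(index=acc, columns=acc).to_numpy(float)
    w = np.linalg.eigvalsh(Kmat)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("kinship matrix is not positive semi-definite")

    value = np.full(n, float(baseline))
    g = genotypes.calls.to_numpy(float)
    for idx, eff in config.causal_snps:
        value = value + eff * np.nan_to_num(g[:, idx], nan=0.0) / 2.0
    if config.causal_gems:
        if log2_expression is None:
            raise ValueError("causal GEMs planted but no expression supplied")
        E = log2_expression.reindex(acc).to_numpy(float)
        for idx, eff in config.causal_gems:
            col = E[:, idx]
            value = value + eff * (col - col.mean())

    h2 = config.h2_polygenic
    if h2 > 0:
        sigma_g2 = h2 / (1.0 - h2) * config.sigma_e**2
        lam, U = np.linalg.eigh(Kmat)
        lam = np.clip(lam, 0.0, None)
        value = value + U @ (np.sqrt(sigma_g2 * lam) * rng.standard_normal(n))

    latent = pd.Series(value, index=acc, name=trait)
    records = []
    for year, offset in sorted(config.year_effects.items()):
        reps = config.reps_per_year.get(year, 1)
        noise = rng.normal(0.0, config.sigma_e, size=(reps, n))
        for r in range(reps):
            records.append(
                pd.DataFrame(
                    {
                        "accession": acc,
                        "year": year,
                        "replicate": r + 1,
                        trait: value + offset + noise[r],
                    }
                )
            )
    return pd.concat(records, ignore_index=True), latent


def simulate_specimens(
    replicate_traits: pd.DataFrame,
    geometry: GeometryConfig | None = None,
    seed: int | np.random.Generator = 0,
    mor_col: str = "MOR",
    moe_col: str = "MOE",
) -> pd.DataFrame:
    """Bend-test specimen records that invert exactly to the given moduli.

    For each replicate row carrying latent MOR and MOE (both > 0), samples
    an annular geometry (outer diameter, hollow fraction; never degenerate),
    computes I, and back-solves the recorded forces:

        Fmax = MOR * I / (a * D2)
        F/V  = MOE * I / ((a^2/12) * (3L - 4a))

    Cross-section areas are emitted consistently with the sampled diameters
    (A = pi D^2 / 4), plus auxiliary morphology columns and a Bernoulli
    breakage flag, giving a complete raw phenotype file.
    """
    geometry = geometry or GeometryConfig()
    rng = _rng(seed)
    n = len(replicate_traits)
    mor = replicate_traits[mor_col].to_numpy(float)
    moe = replicate_traits[moe_col].to_numpy(float)
    if np.any(mor <= 0) or np.any(moe <= 0):
        raise ValueError("latent MOR and MOE must be positive")

    L = geometry.span_L
    a = L / 2.0
    d2 = rng.uniform(*geometry.d2_range, size=n)
    frac = rng.uniform(*geometry.hollow_frac_range, size=n)
    d1a = frac * d2
    I = np.pi * (d2**4 - d1a**4) / 64.0
    fmax = mor * I / (a * d2)
    foverv = moe * I / ((a**2 / 12.0) * (3.0 * L - 4.0 * a))

    out = pd.DataFrame(
        {
            "accession": replicate_traits["accession"].to_numpy(),
            "year": replicate_traits["year"].to_numpy(),
            "replicate": replicate_traits["replicate"].to_numpy(),
            "Fmax": fmax,
            "FoverV": foverv,
            "span_L": L,
            "half_span_a": a,
            "whole_stem_area": np.pi * d2**2 / 4.0,
            "hollow_area": np.pi * d1a**2 / 4.0,
            "parenchyma_area": np.pi * (d2**2 - d1a**2) / 4.0 * rng.uniform(0.5, 0.9, n),
            "cortex_thickness": rng.uniform(0.2, 0.5, n),
            "stem_width": d2,
            "internode2_length": rng.uniform(10.0, 25.0, n),
            "height_minus_ear": rng.uniform(40.0, 100.0, n),
            "stem_weight": rng.uniform(1.0, 4.0, n),
            "threshed_weight": rng.uniform(0.5, 3.0, n),
            "breakage_flag": rng.binomial(1, geometry.breakage_p, size=n),
        }
    )
    return out


def simulate_panel(config: SimulationConfig) -> dict:
    """Run the whole generator, returning every artifact plus the truth.

    Stages receive independent child streams spawned from the master seed,
    so the panel is bit-reproducible and stages are individually stable.
    Phenotypes: the planted causal architecture drives the modulus of
    rupture; the modulus of elasticity is an affine transform of the same
    latent strength plus independent noise, giving the two moduli a
    realistic positive correlation.
    """
    config.validate()
    from .population_structure import kinship_ibs

    children = np.random.SeedSequence(config.seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in children]

    genotypes, truth = simulate_genotypes(config, rngs[0])
    depths = simulate_read_depths(
        genotypes, config.depth_mean, config.seq_error, rngs[1]
    )
    counts, lengths, totals = simulate_expression(genotypes, config, rngs[2])
    from .marker_scoring import compute_rpkm

    expr = compute_rpkm(counts, lengths, totals)
    log2_rpkm = np.log2(expr.rpkm + 1e-9)
    kin = kinship_ibs(genotypes)

    mor_long, mor_latent = simulate_phenotypes(
        genotypes,
        log2_rpkm,
        kin,
        config,
        seed=rngs[3],
        baseline=config.mor_baseline,
        trait="MOR",
    )
    # MOE shares the latent strength signal, with its own scale and noise
    rng_moe = rngs[4]
    moe_latent = (
        config.moe_baseline
        + config.moe_per_mor * (mor_latent - config.mor_baseline)
        + rng_moe.normal(0.0, config.moe_extra_sd, size=len(mor_latent))
    )
    moe_latent = pd.Series(moe_latent, index=mor_latent.index, name="MOE")
    rep = mor_long.copy()
    rep["MOE"] = (
        moe_latent.reindex(rep["accession"]).to_numpy()
        + config.moe_per_mor * (rep["MOR"].to_numpy() - mor_latent.reindex(rep["accession"]).to_numpy())
    )
    # keep physically meaningful (positive) moduli for the bend-test inversion
    rep["MOR"] = rep["MOR"].clip(lower=0.05)
    rep["MOE"] = rep["MOE"].clip(lower=5.0)
    specimens = simulate_specimens(rep, config.geometry, rngs[5])

    truth.latent_traits = {"MOR": mor_latent, "MOE": moe_latent}
    marker_map = default_marker_map(
        [f"UG{j:05d}" for j in range(config.n_unigenes)], np.random.default_rng(config.seed + 1)
    )
    return {
        "config": config,
        "genotypes": genotypes,
        "truth": truth,
        "depths": depths,
        "counts": counts,
        "lengths": lengths,
        "totals": totals,
        "expression": expr,
        "kinship": kin,
        "phenotypes": rep,
        "specimens": specimens,
        "marker_map": marker_map,
    }
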