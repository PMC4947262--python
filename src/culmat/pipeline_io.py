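"""Serialisation, configuration and the end-to-end pipeline driver.

All tabular artifacts travel as tab-separated text with a header of ids
and ``NA`` for missing values; reads are validated (ragged rows, duplicate
ids, non-numeric cells all raise with the offending line number).  A run
is described by a YAML config; ``run_pipeline`` chains the stages

    simulate -> traits -> callsnps -> gems -> kinship -> structure -> assoc

(any contiguous-from-available subset), writing every artifact plus a
provenance manifest of versions, seeds and content hashes, so identical
configs reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .marker_scoring import call_snps, compute_rpkm, filter_gems, filter_maf
from .mechanics import correlation_table, derive_traits, predicted_means
from .population_structure import (
    best_k,
    evanno_delta_k,
    fit_admixture,
    kinship_ibs,
    q_covariates,
)
from .association_engine import gem_association, snp_association
from .synthetic_panel import SimulationConfig, simulate_panel

logger = logging.getLogger("culmat")

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "run_pipeline",
]

STAGES = ("simulate", "traits", "callsnps", "gems", "kinship", "structure", "assoc")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; round-trips through YAML losslessly."""

    seed: int = 0
    out_dir: str = "culmat_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulation: dict = field(default_factory=dict)
    noise_threshold: float = 0.15
    min_depth: int = 4
    min_maf: float = 0.05
    min_mean_rpkm: float = 0.4
    k_min: int = 1
    k_max: int = 5
    structure_replicates: int = 3
    traits: list[str] = field(default_factory=lambda: ["MOR", "MOE"])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    """Write a numeric matrix as TSV with an id header and NA for missing."""
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_matrix(path, kind: str = "float") -> pd.DataFrame:
    """Read a TSV matrix with validation.

    Rejects ragged rows, duplicate row/column ids and (for numeric kinds)
    non-numeric cells, reporting the 1-based line number of the offence.
    ``NA`` cells become NaN.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row ({len(parts)} fields, expected {ncol})"
                )
            ids.append(parts[0])
            rows.append(parts[1:])
    cols = header[1:]
    if len(set(cols)) != len(cols):
        raise ValueError(f"{path.name}:1: duplicate column id")
    seen = {}
    for lineno, rid in enumerate(ids, start=2):
        if rid in seen:
            raise ValueError(f"{path.name}:{lineno}: duplicate row id {rid!r}")
        seen[rid] = lineno
    df = pd.DataFrame(rows, index=pd.Index(ids, name=header[0]), columns=cols)
    if kind == "str":
        return df.replace("NA", np.nan)
    for lineno, rid in enumerate(ids, start=2):
        row = df.loc[rid]
        converted = pd.to_numeric(row.replace("NA", np.nan), errors="coerce")
        bad = converted.isna() & row.notna() & (row != "NA")
        if bad.any():
            col = bad[bad].index[0]
            raise ValueError(
                f"{path.name}:{lineno}: non-numeric cell in column {col!r}: {row[col]!r}"
            )
    out = df.replace("NA", np.nan).apply(pd.to_numeric)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(s.generate_state(1)[0] % (2**31))
        for stage, s in zip(STAGES, ss)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the in-memory artifacts and writes TSV/CSV/JSON files plus
    ``manifest.json`` into ``config.out_dir``.  A requested stage whose
    upstream artifact is neither computed in this run nor on disk raises,
    naming the stage to run first.
    """
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stages = [s for s in STAGES if s in config.stages]
    art: dict = {}
    written: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str, **kw):
        p = out / name
        if name.endswith(".tsv"):
            write_matrix(df, p, **kw)
        else:
            df.to_csv(p, index=False)
        written[name] = _sha256(p)

    def require(key: str, producer: str):
        if key not in art:
            raise RuntimeError(
                f"stage needs artifact {key!r}; run stage {producer!r} first"
            )

    if "simulate" in stages:
        logger.info("simulate: generating synthetic panel")
        sim_cfg = SimulationConfig(seed=seeds["simulate"], **config.simulation)
        panel = simulate_panel(sim_cfg)
        art.update(panel)
        save_df(panel["genotypes"].calls, "true_genotypes.tsv", index_label="accession")
        depths_long = panel["depths"].to_long()
        depths_long.to_csv(out / "depths.tsv", sep="\t", index=False)
        written["depths.tsv"] = _sha256(out / "depths.tsv")
        save_df(panel["counts"], "counts.tsv", index_label="accession")
        save_df(panel["lengths"].to_frame(), "unigene_lengths.tsv", index_label="unigene")
        save_df(panel["totals"].to_frame(), "totals.tsv", index_label="accession")
        panel["specimens"].to_csv(out / "phenotypes.csv", index=False)
        written["phenotypes.csv"] = _sha256(out / "phenotypes.csv")
        save_df(panel["marker_map"].reset_index(), "marker_map.tsv")
        panel["truth"].to_json(out / "truth.json")
        written["truth.json"] = _sha256(out / "truth.json")

    if "traits" in stages:
        require("specimens", "simulate")
        logger.info("traits: deriving MOR/MOE and predicted means")
        derived = derive_traits(art["specimens"])
        means = predicted_means(derived, traits=None)
        corr = correlation_table(means.dropna(axis=1, how="all"))
        art["derived"], art["trait_means"], art["correlations"] = derived, means, corr
        derived.to_csv(out / "derived_traits.csv", index=False)
        written["derived_traits.csv"] = _sha256(out / "derived_traits.csv")
        save_df(means, "trait_means.tsv", index_label="accession")
        save_df(corr.r, "correlations_r.tsv", index_label="trait")
        save_df(corr.p, "correlations_p.tsv", index_label="trait")

    if "callsnps" in stages:
        require("depths", "simulate")
        logger.info("callsnps: calling and MAF-filtering SNPs")
        called = call_snps(
            art["depths"], noise_threshold=config.noise_threshold,
            min_depth=config.min_depth,
        )
        filtered = filter_maf(called, min_maf=config.min_maf)
        art["snps_raw"], art["snps"] = called, filtered
        logger.info(
            "callsnps: %d sites called, %d pass MAF >= %.2f",
            len(called.markers), len(filtered.markers), config.min_maf,
        )
        save_df(filtered.calls, "genotypes.tsv", index_label="accession")
        save_df(filtered.info, "marker_info.tsv", index_label="marker")

    if "gems" in stages:
        require("counts", "simulate")
        logger.info("gems: RPKM quantification and abundance filter")
        expr = compute_rpkm(art["counts"], art["lengths"], art["totals"])
        gems = filter_gems(expr, min_mean_rpkm=config.min_mean_rpkm)
        art["expression_all"], art["gems"] = expr, gems
        save_df(gems.rpkm, "expression.tsv", index_label="accession")

    if "kinship" in stages:
        require("snps", "callsnps")
        logger.info("kinship: IBS matrix from filtered SNPs")
        kin = kinship_ibs(art["snps"])
        art["kinship_est"] = kin
        save_df(kin, "kinship.tsv", index_label="accession")

    if "structure" in stages:
        require("snps", "callsnps")
        logger.info(
            "structure: admixture K=%d..%d, %d replicates",
            config.k_min, config.k_max, config.structure_replicates,
        )
        logliks: dict[int, list[float]] = {}
        fits = {}
        for K in range(config.k_min, config.k_max + 1):
            logliks[K] = []
            for r in range(config.structure_replicates):
                fit = fit_admixture(
                    art["snps"], K, seed=seeds["structure"] + 1000 * K + r,
                    n_restarts=1,
                )
                logliks[K].append(fit.loglik)
                if K not in fits or fit.loglik > fits[K].loglik:
                    fits[K] = fit
        art["structure_fits"], art["structure_logliks"] = fits, logliks
        if config.k_max - config.k_min >= 2:
            ev = evanno_delta_k(logliks)
            art["evanno"] = ev
            k_hat = best_k(ev)
            save_df(ev.reset_index(), "evanno.tsv")
        else:
            k_hat = max(logliks, key=lambda k: np.mean(logliks[k]))
        art["k_selected"] = k_hat
        logger.info("structure: selected K=%d", k_hat)
        art["qmatrix"] = fits[k_hat].Q
        save_df(fits[k_hat].Q, "qmatrix.tsv", index_label="accession")

    if "assoc" in stages:
        for key, producer in (
            ("snps", "callsnps"), ("gems", "gems"),
            ("kinship_est", "kinship"), ("qmatrix", "structure"),
            ("trait_means", "traits"),
        ):
            require(key, producer)
        qc = q_covariates(art["structure_fits"][art["k_selected"]])
        mmap = art.get("marker_map")
        for trait in config.traits:
            if trait not in art["trait_means"].columns:
                raise RuntimeError(f"trait {trait!r} absent from trait means")
            logger.info("assoc: trait %s", trait)
            y = art["trait_means"][trait]
            snp_tab = snp_association(
                y, art["snps"], qc, art["kinship_est"], marker_map=mmap
            )
            gem_tab = gem_association(y, art["gems"], marker_map=mmap)
            art[f"snp_assoc_{trait}"] = snp_tab
            art[f"gem_assoc_{trait}"] = gem_tab
            snp_tab.to_csv(out / f"snp_assoc_{trait}.tsv", sep="\t", index=False)
            gem_tab.to_csv(out / f"gem_assoc_{trait}.tsv", sep="\t", index=False)
            written[f"snp_assoc_{trait}.tsv"] = _sha256(out / f"snp_assoc_{trait}.tsv")
            written[f"gem_assoc_{trait}.tsv"] = _sha256(out / f"gem_assoc_{trait}.tsv")

    manifest = {
        "culmat_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: seeds[s] for s in stages},
        "stages": stages,
        "outputs": written,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    art["manifest"] = manifest
    return art
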