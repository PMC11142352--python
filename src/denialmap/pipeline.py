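"""End-to-end orchestration: ingest -> Moran screen -> BYM fit -> RR metrics.

One declarative config drives the whole run.  Each MSA is processed
independently; a failure in one MSA is logged and quarantined without
stopping the others.  All outputs are written atomically (temp file, then
rename) so a crash never leaves a truncated file in a final path.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bym import BYMModelSpec, fit_msa
from .ingest import prepare_analysis
from .metrics import summarize_msa, write_estimates_csv, write_estimates_geojson
from .spatial import TractGeometry, build_adjacency, moran_i, read_edge_list
from .synthetic import SyntheticConfig, generate

log = logging.getLogger("denialmap")

__all__ = [
    "RunConfig",
    "run_pipeline",
    "run_recovery_study",
    "run_sbc_study",
    "sbc_rank_pvalues",
    "atomic_write",
]


def atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename into place."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        Path(tmp).unlink(missing_ok=True)
        raise


@dataclass
class RunConfig:
    """Declarative settings for a full pipeline run.  ``seed`` is mandatory."""

    lar_path: str
    output_dir: str
    seed: int
    geometry_path: str | None = None  # GeoJSON tract polygons
    edge_list_path: str | None = None  # or a precomputed adjacency edge list
    column_map: dict[str, str] = field(default_factory=dict)
    moran_permutations: int = 999
    moran_alpha: float = 0.05
    moran_variable: str = "crude_rate"
    moran_row_standardize: bool = False
    classification_rule: str = "point"
    model: dict[str, Any] = field(default_factory=dict)  # BYMModelSpec overrides
    n_chains: int = 4
    n_iter: int = 5000
    burn_in: int = 2500
    thin: int = 1
    msa_include: list[str] | None = None
    msa_exclude: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required; refusing to run without one")
        if not Path(self.lar_path).exists():
            raise FileNotFoundError(self.lar_path)
        if self.geometry_path is None and self.edge_list_path is None:
            raise ValueError("config needs geometry_path or edge_list_path")
        for p in (self.geometry_path, self.edge_list_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)

    def msa_seed(self, msa_id: str) -> int:
        # independent of worker count and of which other MSAs are present
        return int((self.seed * 2654435761 + zlib.crc32(msa_id.encode())) % (2**31))

    def model_spec(self) -> BYMModelSpec:
        kwargs = dict(self.model)
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return BYMModelSpec(**kwargs)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_geometry(config: RunConfig) -> TractGeometry | None:
    if config.geometry_path:
        return TractGeometry.from_geojson(config.geometry_path)
    return None


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run ingest -> adjacency -> Moran -> BYM -> metrics for every MSA.

    Returns a manifest dict (also written to ``output_dir/manifest.json``).
    Raises ``RuntimeError`` only if every MSA fails.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, counts, report = prepare_analysis(config.lar_path, config.column_map or None)
    log.info("ingest: %d rows in, %d analysis records", report.rows_in, report.retained)
    atomic_write(outdir / "filter_report.json", lambda p: p.write_text(report.to_json()))

    geometry = _load_geometry(config)

    msas = sorted(records["msa_id"].dropna().unique())
    if config.msa_include is not None:
        msas = [m for m in msas if m in set(config.msa_include)]
    msas = [m for m in msas if m not in set(config.msa_exclude)]

    moran_rows, summary_rows, failures = [], [], {}
    for msa in msas:
        try:
            result = _run_one_msa(config, msa, records, counts, geometry, outdir)
            moran_rows.append(result["moran_row"])
            summary_rows.append(result["summary_row"])
        except Exception as exc:  # quarantine this MSA, keep going
            log.exception("MSA %s failed", msa)
            failures[str(msa)] = f"{type(exc).__name__}: {exc}"
    if msas and not moran_rows and failures:
        raise RuntimeError(f"all {len(msas)} MSA(s) failed: {failures}")

    atomic_write(
        outdir / "moran.csv",
        lambda p: pd.DataFrame(moran_rows).to_csv(p, index=False),
    )
    atomic_write(
        outdir / "msa_summaries.csv",
        lambda p: pd.DataFrame(summary_rows).to_csv(p, index=False),
    )
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_msas_fit": len(summary_rows),
        "failures": failures,
    }
    atomic_write(
        outdir / "manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2))
    )
    return manifest


def _run_one_msa(
    config: RunConfig,
    msa: str,
    records: pd.DataFrame,
    counts: pd.DataFrame,
    geometry: TractGeometry | None,
    outdir: Path,
) -> dict[str, Any]:
    msa_records = records[records["msa_id"] == msa]
    msa_counts = counts[counts["msa_id"] == msa]
    if msa_records["tract_geoid"].nunique() < 2:
        raise ValueError("fewer than 2 populated tracts")

    msa_geom = geometry.subset_msa(msa) if geometry is not None else None
    if msa_geom is not None and len(msa_geom):
        adjacency = build_adjacency(msa_geom)
    else:
        observed = sorted(msa_records["tract_geoid"].unique())
        adjacency = read_edge_list(config.edge_list_path, ids=None)
        keep = [g for g in adjacency.ids if g in set(observed)] or observed
        adjacency = adjacency.subset(keep)

    # Moran screen on the configured surface (default: crude denial rate),
    # restricted to tracts with at least one eligible loan
    rate = msa_counts.set_index("tract_geoid")[config.moran_variable]
    present = [g for g in adjacency.ids if g in rate.index]
    moran_adj = adjacency.subset(present)
    moran = moran_i(
        rate.loc[present].to_numpy(float),
        moran_adj,
        n_permutations=config.moran_permutations,
        alpha=config.moran_alpha,
        seed=config.msa_seed(msa),
        row_standardize=config.moran_row_standardize,
    )
    log.info("MSA %s: Moran I=%.3f p=%.3f", msa, moran.I, moran.p_value)

    # tracts in the graph but without loans stay as prediction-only nodes
    draws, estimates = fit_msa(
        msa_records,
        adjacency,
        spec=config.model_spec(),
        n_chains=config.n_chains,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        thin=config.thin,
        seed=config.msa_seed(msa),
    )
    for e in estimates:
        e.rule = config.classification_rule
        from .metrics import classify_tract

        e.classification = classify_tract(e, config.classification_rule)
    summary = summarize_msa(estimates, moran=moran, rule=config.classification_rule)

    msa_dir = outdir / f"msa_{msa}"
    msa_dir.mkdir(exist_ok=True)
    atomic_write(msa_dir / "tract_estimates.csv", lambda p: write_estimates_csv(estimates, p))
    if msa_geom is not None and len(msa_geom):
        atomic_write(
            msa_dir / "tract_estimates.geojson",
            lambda p: write_estimates_geojson(estimates, msa_geom, p),
        )
    draws.save(msa_dir / "draws")

    moran_row = {
        "msa_id": msa,
        "n_tracts": moran.n,
        "moran_i": moran.I,
        "expected": moran.expected,
        "p_value": moran.p_value,
        "significant": moran.significant,
    }
    summary_row = {
        "msa_id": msa,
        "n_tracts": summary.n_tracts,
        "proportion_elevated": summary.proportion_elevated,
        "median_cri_width": summary.median_cri_width,
        "iqr_cri_width": summary.iqr_cri_width,
        "rule": summary.rule,
        "converged": draws.meta.get("converged"),
    }
    return {"moran_row": moran_row, "summary_row": summary_row}


def run_recovery_study(
    synthetic_config: SyntheticConfig | None = None,
    n_replicates: int = 50,
    n_chains: int = 1,
    n_iter: int = 800,
    burn_in: int = 400,
    seed: int = 0,
    spec: BYMModelSpec | None = None,
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """Repeated simulate-then-fit parameter-recovery study.

    Each replicate generates a dataset from ``synthetic_config`` (fresh seed
    per replicate), fits the first MSA's model, and records posterior means,
    95% CrI coverage of the true (alpha, beta_sex, beta_lti), and the
    Spearman rank correlation between true and estimated tract RR.  Returns
    one row per replicate; write the table with ``output_path``.
    """
    from scipy.stats import spearmanr

    base = synthetic_config or SyntheticConfig()
    spec = spec or BYMModelSpec()
    rows = []
    for rep in range(n_replicates):
        cfg = SyntheticConfig(**{**asdict_config(base), "seed": int((seed * 100003 + rep) % 2**31)})
        ds = generate(cfg)
        msa = ds.geometry.msas[0]
        loans = ds.loans[ds.loans["msa_id"] == msa]
        draws, estimates = fit_msa(
            loans,
            ds.adjacency[msa],
            spec=spec,
            n_chains=n_chains,
            n_iter=n_iter,
            burn_in=burn_in,
            seed=int((seed * 7919 + rep) % 2**31),
        )
        alpha_d = draws.stacked("alpha")
        beta_d = draws.stacked("beta")
        truth_msa = ds.truth[ds.truth["msa_id"] == msa].set_index("tract_geoid")
        true_rr = np.exp(
            truth_msa.loc[[e.tract_geoid for e in estimates], "u"].to_numpy()
            + truth_msa.loc[[e.tract_geoid for e in estimates], "v"].to_numpy()
        )
        est_rr = np.array([e.rr_mean for e in estimates])
        rho = float(spearmanr(true_rr, est_rr).statistic) if len(est_rr) > 2 else np.nan
        row = {
            "replicate": rep,
            "alpha_true": cfg.alpha,
            "alpha_mean": float(alpha_d.mean()),
            "alpha_covered": _covered(alpha_d, cfg.alpha),
            "rr_spearman": rho,
        }
        for k, name in enumerate(spec.covariates):
            truth_val = {"sex_female": cfg.beta_sex, "lti": cfg.beta_lti}[name]
            row[f"beta_{name}_true"] = truth_val
            row[f"beta_{name}_mean"] = float(beta_d[:, k].mean())
            row[f"beta_{name}_covered"] = _covered(beta_d[:, k], truth_val)
        rows.append(row)
    table = pd.DataFrame(rows)
    if output_path is not None:
        atomic_write(Path(output_path), lambda p: table.to_csv(p, index=False))
    return table


def run_sbc_study(
    n_replicates: int = 200,
    grid_rows: int = 5,
    grid_cols: int = 5,
    loans_per_tract: int = 30,
    n_iter: int = 650,
    burn_in: int = 250,
    thin: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulation-based calibration of the Gibbs sampler.

    Each replicate draws (alpha, beta, sigma_u^2, sigma_v^2, u, v) from
    proper priors, simulates loans from the drawn parameters, fits the model
    under the *same* priors, and records the rank of each true value among
    the thinned posterior draws.  If the sampler targets the correct
    posterior the ranks are discrete-uniform; deviations show up in a
    chi-square test on the rank histogram.

    Priors here are deliberately proper and moderately informative (alpha ~
    N(logit 0.103, 1), beta ~ N(0, 0.25), precisions ~ Gamma(2, 1)) so every
    replicate's dataset is a plausible denial surface; SBC validity only
    requires that the generator and the model share these priors exactly.
    Returns one row per replicate with columns ``rank_<parameter>`` in
    ``0 .. n_kept`` where ``n_kept = (n_iter - burn_in) // thin``.
    """
    from .bym import ModelData, sample_posterior
    from .synthetic import draw_icar, logit, make_lattice, simulate_loans

    spec = BYMModelSpec(
        alpha_prior_mean=logit(0.103),
        alpha_prior_var=1.0,
        beta_prior_var=0.25,
        tau_u_shape=2.0,
        tau_u_rate=1.0,
        tau_v_shape=2.0,
        tau_v_rate=1.0,
    )
    base = SyntheticConfig(
        n_msa=1, grid_rows=grid_rows, grid_cols=grid_cols,
        loans_per_tract=loans_per_tract, seed=seed,
    )
    geom, adjd = make_lattice(base)
    msa = geom.msas[0]
    adj = adjd[msa]
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        tau_u = rng.gamma(spec.tau_u_shape, 1.0 / spec.tau_u_rate)
        tau_v = rng.gamma(spec.tau_v_shape, 1.0 / spec.tau_v_rate)
        s2u, s2v = 1.0 / tau_u, 1.0 / tau_v
        alpha = rng.normal(spec.alpha_prior_mean, np.sqrt(spec.alpha_prior_var))
        beta_sex, beta_lti = rng.normal(0.0, np.sqrt(spec.beta_prior_var), 2)
        cfg = SyntheticConfig(
            **{
                **asdict_config(base),
                "alpha": float(alpha),
                "beta_sex": float(beta_sex),
                "beta_lti": float(beta_lti),
                "sigma2_u": float(s2u),
                "sigma2_v": float(s2v),
                "seed": int(rng.integers(2**31)),
            }
        )
        u = draw_icar(adj, s2u, np.random.default_rng(int(rng.integers(2**31))))
        v = np.random.default_rng(int(rng.integers(2**31))).normal(
            0.0, np.sqrt(s2v), adj.n
        )
        ds = simulate_loans(cfg, geom, u, v)
        data = ModelData.from_records(ds.loans, adj, spec.covariates)
        draws = sample_posterior(
            data, spec, n_chains=1, n_iter=n_iter, burn_in=burn_in, thin=thin,
            seed=int(rng.integers(2**31)),
        )
        truth = {
            "alpha": alpha,
            "beta_sex": beta_sex,
            "beta_lti": beta_lti,
            "sigma2_u": s2u,
            "sigma2_v": s2v,
        }
        post = {
            "alpha": draws.stacked("alpha"),
            "beta_sex": draws.stacked("beta")[:, 0],
            "beta_lti": draws.stacked("beta")[:, 1],
            "sigma2_u": draws.stacked("sigma2_u"),
            "sigma2_v": draws.stacked("sigma2_v"),
        }
        rows.append(
            {"replicate": rep}
            | {f"rank_{k}": int((post[k] < truth[k]).sum()) for k in truth}
        )
    return pd.DataFrame(rows)


def sbc_rank_pvalues(ranks: pd.DataFrame, n_kept: int, n_bins: int = 13) -> dict[str, float]:
    """Chi-square uniformity p-value of each rank column over equal bins."""
    from scipy.stats import chisquare

    out = {}
    edges = np.linspace(0, n_kept + 1, n_bins + 1)
    for col in [c for c in ranks.columns if c.startswith("rank_")]:
        hist, _ = np.histogram(ranks[col].to_numpy(), bins=edges)
        out[col.removeprefix("rank_")] = float(chisquare(hist).pvalue)
    return out


def _covered(draws: np.ndarray, truth: float, level: float = 0.95) -> bool:
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
    return bool(lo <= truth <= hi)


def asdict_config(cfg: SyntheticConfig) -> dict:
    from dataclasses import asdict as _asdict

    return _asdict(cfg)
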