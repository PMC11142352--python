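"""Synthetic loan-level data from the exact generative model the analysis assumes.

Each metropolitan area (MSA) is a planar lattice of unit-square census
tracts with queen-contiguity adjacency.  Tract-level residual risk is the
Besag-York-Mollie decomposition u + v: u drawn from the intrinsic CAR
(ICAR) distribution constrained to sum to zero within each connected
component, v i.i.d. normal.  Loan applications carry an applicant-sex
indicator and a log-normal loan-to-income ratio, and denial is Bernoulli
through the logit link

    logit(theta_ij) = alpha + beta_sex * sex_i + beta_lti * lti_i + u_j + v_j.

True parameter values travel with the dataset so that every downstream
stage (ingestion round-trip, Moran screening, posterior recovery) can be
tested against known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from shapely.geometry import box

from .spatial import AdjacencyStructure, TractGeometry, build_adjacency

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_lattice",
    "draw_icar",
    "simulate_loans",
    "generate",
    "logit",
    "expit",
]

# paper-anchored default baseline: overall denial is rare, ~10.3%
DEFAULT_DENIAL_RATE = 0.103


def logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


LoansPerTract = Union[int, tuple[str, float]]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults define the reference synthetic regime.

    ``loans_per_tract`` is either a fixed positive integer or
    ``("poisson", mean)`` with a floor of one loan per tract.
    ``alpha`` defaults to logit(0.103), the rare-denial baseline.
    """

    n_msa: int = 2
    grid_rows: int = 5
    grid_cols: int = 5
    loans_per_tract: LoansPerTract = 50
    alpha: float = field(default_factory=lambda: logit(DEFAULT_DENIAL_RATE))
    beta_sex: float = 0.25
    beta_lti: float = 0.10
    sigma2_u: float = 0.25
    sigma2_v: float = 0.05
    p_female: float = 0.30
    lti_mu: float = 0.7  # log-normal location: median LTI ~ 2.0
    lti_sigma: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_msa < 1:
            raise ValueError("n_msa must be >= 1")
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("each MSA needs at least 2 tracts (ICAR undefined otherwise)")
        if self.sigma2_u < 0 or self.sigma2_v < 0:
            raise ValueError("variances must be non-negative")
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must be in [0, 1]")
        if isinstance(self.loans_per_tract, int):
            if self.loans_per_tract < 1:
                raise ValueError("loans_per_tract must be >= 1")
        else:
            kind, mean = self.loans_per_tract
            if kind != "poisson" or mean <= 0:
                raise ValueError("loans_per_tract spec must be an int or ('poisson', mean>0)")

    @property
    def n_tracts_per_msa(self) -> int:
        return self.grid_rows * self.grid_cols

    def msa_id(self, m: int) -> str:
        return f"{10180 + 40 * m:05d}"

    def msa_rng(self, m: int, stream: str = "loans") -> np.random.Generator:
        """Deterministic per-MSA substream: adding MSAs never perturbs others."""
        key = zlib.crc32(f"{self.msa_id(m)}/{stream}".encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class SyntheticDataset:
    """Loans plus the geometry, adjacency and ground truth that produced them."""

    loans: pd.DataFrame
    geometry: TractGeometry
    adjacency: dict[str, AdjacencyStructure]  # per MSA
    truth: pd.DataFrame  # tract_geoid, msa_id, u, v
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write loans in the public LAR CSV schema, geometry as GeoJSON, and
        the truth table as a separate CSV never read by the pipeline."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "loans": outdir / "loans.csv",
            "geometry": outdir / "tracts.geojson",
            "truth": outdir / "truth.csv",
        }
        to_lar_frame(self.loans).to_csv(paths["loans"], index=False)
        self.geometry.to_geojson(paths["geometry"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _tract_geoid(msa_index: int, tract_index: int) -> str:
    # synthetic FIPS: state 01, county = MSA ordinal, tract = (k+1)*100
    return f"01{msa_index + 1:03d}{(tract_index + 1) * 100:06d}"


def make_lattice(config: SyntheticConfig) -> tuple[TractGeometry, dict[str, AdjacencyStructure]]:
    """Unit-square tract lattices, one per MSA, with queen-contiguity adjacency.

    MSAs are separated by a one-unit gap so no cross-MSA edges can arise;
    adjacency is computed from the polygons themselves (shared edge or corner).
    """
    geoids: list[str] = []
    msa_ids: list[str] = []
    polys = []
    for m in range(config.n_msa):
        x0 = m * (config.grid_cols + 2)  # >= 1-unit gap between MSAs
        for r in range(config.grid_rows):
            for c in range(config.grid_cols):
                k = r * config.grid_cols + c
                geoids.append(_tract_geoid(m, k))
                msa_ids.append(config.msa_id(m))
                polys.append(box(x0 + c, r, x0 + c + 1, r + 1))
    geometry = TractGeometry(geoids, msa_ids, polys)
    adjacency = {
        msa: build_adjacency(geometry.subset_msa(msa)) for msa in geometry.msas
    }
    for msa, adj in adjacency.items():
        if adj.n == 1:
            raise ValueError(f"MSA {msa} has a single tract; ICAR undefined")
    return geometry, adjacency


def draw_icar(
    adjacency: AdjacencyStructure,
    sigma2_u: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One draw from the intrinsic CAR distribution on the graph.

    The ICAR density is proportional to
    exp(-(1/(2 sigma_u^2)) * sum_{g~j} (u_g - u_j)^2 / 2) — a degenerate
    Gaussian with precision Laplacian/sigma_u^2.  We sample its proper
    restriction to the sum-to-zero subspace of each connected component via
    the spectral decomposition of the Laplacian: independent N(0, sigma_u^2 /
    lambda_k) weights on the non-null eigenvectors.  The draw therefore sums
    to zero within every component to machine precision, and has covariance
    sigma_u^2 * L^+ (Moore-Penrose pseudo-inverse of the Laplacian).
    Disconnected graphs are handled automatically: the null space of L is
    spanned by per-component indicators, so centering is per component.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = adjacency.n
    if sigma2_u == 0.0:
        return np.zeros(n)
    L = adjacency.laplacian().toarray()
    eigval, eigvec = np.linalg.eigh(L)
    # null space dimension == number of connected components
    tol = n * np.finfo(float).eps * max(eigval.max(), 1.0)
    positive = eigval > tol
    z = rng.standard_normal(int(positive.sum()))
    u = eigvec[:, positive] @ (z * np.sqrt(sigma2_u / eigval[positive]))
    return u


def simulate_loans(
    config: SyntheticConfig,
    geometry: TractGeometry,
    u: np.ndarray,
    v: np.ndarray,
) -> SyntheticDataset:
    """Bernoulli denial outcomes through the logit link, given tract effects.

    ``u`` and ``v`` are indexed by tract in ``geometry`` order (one entry per
    tract across all MSAs).  Loan covariates and outcomes are drawn from
    per-MSA substreams of ``config.seed``.
    """
    n_tracts = len(geometry)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != (n_tracts,) or v.shape != (n_tracts,):
        raise ValueError("u and v must have one entry per tract in geometry order")

    frames = []
    for m, msa in enumerate(geometry.msas):
        idx = [i for i, mm in enumerate(geometry.msa_ids) if mm == msa]
        rng = config.msa_rng(m, "loans")
        per_tract_rows = []
        for i in idx:
            if isinstance(config.loans_per_tract, int):
                n_loans = config.loans_per_tract
            else:
                n_loans = max(1, int(rng.poisson(config.loans_per_tract[1])))
            per_tract_rows.append((i, n_loans))
        total = sum(n for _, n in per_tract_rows)
        tract_idx = np.repeat([i for i, _ in per_tract_rows], [n for _, n in per_tract_rows])
        sex = rng.random(total) < config.p_female
        lti = np.exp(rng.normal(config.lti_mu, config.lti_sigma, size=total))
        income = np.exp(rng.normal(4.3, 0.5, size=total))  # thousands of dollars
        eta = (
            config.alpha
            + config.beta_sex * sex
            + config.beta_lti * lti
            + u[tract_idx]
            + v[tract_idx]
        )
        denied = rng.random(total) < expit(eta)
        frames.append(
            pd.DataFrame(
                {
                    "msa_id": msa,
                    "tract_geoid": np.array(geometry.geoids, dtype=object)[tract_idx],
                    "sex_female": sex.astype(int),
                    "lti": lti,
                    "applicant_income": income,
                    "loan_amount": lti * income,
                    "denied": denied.astype(int),
                }
            )
        )
    loans = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "tract_geoid": geometry.geoids,
            "msa_id": geometry.msa_ids,
            "u": u,
            "v": v,
        }
    )
    adjacency = {msa: build_adjacency(geometry.subset_msa(msa)) for msa in geometry.msas}
    return SyntheticDataset(
        loans=loans, geometry=geometry, adjacency=adjacency, truth=truth, config=config
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """End-to-end draw: lattice, ICAR u, i.i.d. v, then loans."""
    geometry, adjacency = make_lattice(config)
    u = np.empty(len(geometry))
    v = np.empty(len(geometry))
    for m, msa in enumerate(geometry.msas):
        idx = np.array([i for i, mm in enumerate(geometry.msa_ids) if mm == msa])
        rng_u = config.msa_rng(m, "icar")
        rng_v = config.msa_rng(m, "iid")
        u[idx] = draw_icar(adjacency[msa], config.sigma2_u, rng_u)
        v[idx] = rng_v.normal(0.0, np.sqrt(config.sigma2_v), size=idx.size)
    return simulate_loans(config, geometry, u, v)


def to_lar_frame(loans: pd.DataFrame) -> pd.DataFrame:
    """Render analysis loans in the public 2010-2014 LAR CSV schema.

    All rows are eligible home-purchase, owner-occupied, 1-4 family records;
    denial maps to action code 3 and approval to code 1 (loan originated), so
    the real reader reproduces the generator's loans exactly.
    """
    geoid = loans["tract_geoid"].astype(str)
    tract_num = geoid.str[5:9].astype(int).astype(str) + "." + geoid.str[9:11]
    return pd.DataFrame(
        {
            "action_taken": np.where(loans["denied"] == 1, 3, 1),
            "loan_purpose": 1,
            "property_type": 1,
            "owner_occupancy": 1,
            "loan_amount_000s": loans["loan_amount"].to_numpy(),
            "applicant_income_000s": loans["applicant_income"].to_numpy(),
            "applicant_sex": np.where(loans["sex_female"] == 1, 2, 1),
            "msamd": loans["msa_id"].astype(str),
            "state_code": geoid.str[0:2],
            "county_code": geoid.str[2:5],
            "census_tract_number": tract_num,
        }
    )
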