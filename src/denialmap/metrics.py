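"""Tract-level relative ratios of mortgage denial and MSA summaries.

The quantity of interest is the exponentiated area-level residual
RR_j = exp(u_j + v_j): the tract's denial risk relative to the MSA average
after adjusting for loan-level covariates.  RR > 1 marks elevated risk,
RR in (0, 1) decreased risk.  Summaries use the posterior mean and the
equal-tailed 95% credible interval computed on the exponentiated scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bym import PosteriorDraws
from .spatial import MoranResult, TractGeometry

__all__ = [
    "TractRiskEstimate",
    "MsaSummary",
    "relative_ratio",
    "relative_ratios",
    "classify_tract",
    "summarize_msa",
    "estimates_to_frame",
    "write_estimates_csv",
    "write_estimates_geojson",
]


@dataclass
class TractRiskEstimate:
    """Posterior summary of one tract's relative ratio exp(u_j + v_j)."""

    tract_geoid: str
    msa_id: str
    rr_mean: float
    rr_lower: float  # 2.5th posterior percentile
    rr_upper: float  # 97.5th posterior percentile
    cri_width: float
    rr_sd: float
    classification: str = "null"
    rule: str = "point"


@dataclass
class MsaSummary:
    msa_id: str
    n_tracts: int
    proportion_elevated: float
    median_cri_width: float
    iqr_cri_width: float
    rule: str
    moran: MoranResult | None = None


def relative_ratio(
    draws: PosteriorDraws,
    tract_geoid: str,
    msa_id: str = "",
    rule: str = "point",
    level: float = 0.95,
) -> TractRiskEstimate:
    """Summarize exp(u_j + v_j) for one tract from pooled posterior draws."""
    s = draws.linear_effect(tract_geoid)  # raises KeyError if absent
    rr = np.exp(s)
    lo, hi = np.quantile(rr, [(1 - level) / 2, 1 - (1 - level) / 2])
    est = TractRiskEstimate(
        tract_geoid=tract_geoid,
        msa_id=msa_id,
        rr_mean=float(rr.mean()),
        rr_lower=float(lo),
        rr_upper=float(hi),
        cri_width=float(hi - lo),
        rr_sd=float(rr.std(ddof=1)),
        rule=rule,
    )
    est.classification = classify_tract(est, rule)
    return est


def relative_ratios(
    draws: PosteriorDraws, msa_id: str = "", rule: str = "point"
) -> list[TractRiskEstimate]:
    return [relative_ratio(draws, g, msa_id=msa_id, rule=rule) for g in draws.tract_ids]


def classify_tract(estimate: TractRiskEstimate, rule: str = "point") -> str:
    """Elevated / decreased / null classification of a tract's RR.

    ``point`` (default): elevated iff the posterior mean exceeds 1, decreased
    iff below 1, null exactly at 1.  ``interval``: elevated iff the lower
    95% bound exceeds 1, decreased iff the upper bound is below 1.
    """
    if rule == "point":
        if estimate.rr_mean > 1.0:
            return "elevated"
        if estimate.rr_mean < 1.0:
            return "decreased"
        return "null"
    if rule == "interval":
        if estimate.rr_lower > 1.0:
            return "elevated"
        if estimate.rr_upper < 1.0:
            return "decreased"
        return "null"
    raise ValueError(f"unknown classification rule {rule!r}")


def summarize_msa(
    estimates: list[TractRiskEstimate],
    moran: MoranResult | None = None,
    rule: str = "point",
    precision: str = "cri_width",
) -> MsaSummary:
    """MSA rollup: share of elevated tracts and the precision distribution.

    ``precision`` selects the spread measure summarized across tracts:
    the 95% credible-interval width (default) or the posterior SD of RR.
    """
    if not estimates:
        raise ValueError("no tract estimates to summarize")
    labels = [classify_tract(e, rule) for e in estimates]
    if precision == "cri_width":
        widths = np.array([e.cri_width for e in estimates])
    elif precision == "posterior_sd":
        widths = np.array([e.rr_sd for e in estimates])
    else:
        raise ValueError(f"unknown precision measure {precision!r}")
    q25, q50, q75 = np.percentile(widths, [25, 50, 75])
    return MsaSummary(
        msa_id=estimates[0].msa_id,
        n_tracts=len(estimates),
        proportion_elevated=sum(lab == "elevated" for lab in labels) / len(labels),
        median_cri_width=float(q50),
        iqr_cri_width=float(q75 - q25),
        rule=rule,
        moran=moran,
    )


def estimates_to_frame(estimates: list[TractRiskEstimate]) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in estimates])


def write_estimates_csv(estimates: list[TractRiskEstimate], path: str | Path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def write_estimates_geojson(
    estimates: list[TractRiskEstimate],
    geometry: TractGeometry,
    path: str | Path,
) -> None:
    """Join estimates onto tract polygons for choropleth mapping in any GIS."""
    from shapely.geometry import mapping as shapely_mapping

    by_geoid = {e.tract_geoid: e for e in estimates}
    features = []
    for geoid, msa, poly in zip(geometry.geoids, geometry.msa_ids, geometry.polygons):
        est = by_geoid.get(geoid)
        if est is None:
            continue
        features.append(
            {
                "type": "Feature",
                "properties": asdict(est),
                "geometry": shapely_mapping(poly),
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
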