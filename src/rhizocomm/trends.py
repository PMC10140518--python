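"""Beta-regression trend classification of phylum relative abundances.

Each phylum's per-sample relative abundance y (a proportion) is modeled as
Beta(mu * phi, (1 - mu) * phi) with logit(mu) = b0 + b1 * x, where x codes
an ordered gradient 0/1/2 — spatial (bulk -> rhizosphere -> rhizoplane) or
temporal (tillering -> heading -> mature).  The Wald test on b1 calls each
phylum increasing (b1 > 0, p < 0.05), decreasing (b1 < 0, p < 0.05) or
flat.  Boundary proportions are shrunk with the usual
(y * (n - 1) + 0.5) / n adjustment because the beta likelihood is
undefined at exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

from rhizocomm.matrix import (
    COMPARTMENTS,
    STAGES,
    CommunityMatrix,
    SampleMetadata,
    TaxonomyTable,
)

SPATIAL_CODES = {c: i for i, c in enumerate(COMPARTMENTS)}
TEMPORAL_CODES = {s: i for i, s in enumerate(STAGES)}


@dataclass
class TrendFit:
    """One phylum's fitted abundance trend along a gradient."""

    phylum: str
    gradient: str  # "spatial" | "temporal"
    compartment: str | None  # set for temporal fits (one per compartment)
    slope: float  # b1 on the logit scale
    stderr: float
    z: float
    p_value: float
    precision: float  # phi
    direction: str  # "increasing" | "decreasing" | "flat"
    log_likelihood: float
    n: int


def _direction(slope: float, p: float, alpha: float) -> str:
    if p < alpha and slope > 0:
        return "increasing"
    if p < alpha and slope < 0:
        return "decreasing"
    return "flat"


def smithson_verkuilen(y: np.ndarray) -> np.ndarray:
    """Shrink proportions off the 0/1 boundary: (y(n-1) + 0.5) / n."""
    n = y.size
    return (y * (n - 1) + 0.5) / n


def beta_regression_fit(
    y,
    x,
    gradient: str = "spatial",
    phylum: str = "",
    compartment: str | None = None,
    alpha: float = 0.05,
) -> TrendFit:
    """Maximum-likelihood beta regression of proportions on gradient codes.

    Logit mean link, constant precision phi (log link internally).  Raises
    on non-convergence or on responses outside [0, 1].  The boundary
    adjustment is applied only when a 0 or 1 actually occurs.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("y and x must have equal length")
    if y.size < 6:
        raise ValueError("need at least 6 observations")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must be proportions in [0, 1]")
    if ((y == 0) | (y == 1)).any():
        y = smithson_verkuilen(y)
    if np.ptp(y) == 0:
        # a constant response is the degenerate phi -> inf limit: no trend
        return TrendFit(
            phylum=phylum,
            gradient=gradient,
            compartment=compartment,
            slope=0.0,
            stderr=float("inf"),
            z=0.0,
            p_value=1.0,
            precision=float("inf"),
            direction="flat",
            log_likelihood=float("nan"),
            n=int(y.size),
        )
    exog = sm.add_constant(x)
    model = BetaModel(y, exog)
    with np.errstate(all="ignore"):
        res = model.fit(disp=False)

    def _ok(r) -> bool:
        # BFGS sometimes flags precision loss at a stationary point;
        # accept any solution whose gradient is effectively zero
        if r.mle_retvals.get("converged", True):
            return True
        grad = r.mle_retvals.get("gopt")
        return grad is not None and np.max(np.abs(grad)) < 1e-3

    if not _ok(res):
        with np.errstate(all="ignore"):
            start = model.fit(method="nm", maxiter=2000, disp=False).params
            res = model.fit(start_params=start, disp=False)
    if not _ok(res):
        raise RuntimeError(
            f"beta regression did not converge for phylum {phylum!r}: "
            f"{res.mle_retvals}"
        )
    slope = float(res.params[1])
    se = float(res.bse[1])
    z = slope / se
    p = float(res.pvalues[1])
    # precision is fit on the log scale
    phi = float(np.exp(res.params[-1]))
    return TrendFit(
        phylum=phylum,
        gradient=gradient,
        compartment=compartment,
        slope=slope,
        stderr=se,
        z=float(z),
        p_value=p,
        precision=phi,
        direction=_direction(slope, p, alpha),
        log_likelihood=float(res.llf),
        n=int(y.size),
    )


def phylum_relative_abundance(
    m: CommunityMatrix, taxonomy: TaxonomyTable
) -> pd.DataFrame:
    """Aggregate the matrix to phylum x sample relative abundances.

    Taxa with no phylum annotation aggregate under the explicit empty
    marker rather than being mixed into a named phylum.
    """
    rel = m.relative_abundance().data
    phylum = taxonomy.phylum().reindex(rel.index).fillna("")
    return rel.groupby(phylum.values).sum()


def classify_trends(
    m: CommunityMatrix,
    taxonomy: TaxonomyTable,
    meta: SampleMetadata,
    gradient: str = "spatial",
    alpha: float = 0.05,
    min_mean_abundance: float = 0.0,
) -> list[TrendFit]:
    """Fit a beta-regression trend per phylum.

    ``gradient="spatial"`` codes compartments 0/1/2 and pools all samples;
    ``gradient="temporal"`` codes stages 0/1/2 and fits within each
    compartment separately.  Phyla absent everywhere (or below
    ``min_mean_abundance``) are skipped.
    """
    if gradient not in ("spatial", "temporal"):
        raise ValueError("gradient must be 'spatial' or 'temporal'")
    by_phylum = phylum_relative_abundance(m, taxonomy)
    by_phylum = by_phylum[by_phylum.sum(axis=1) > 0]
    by_phylum = by_phylum[by_phylum.mean(axis=1) >= min_mean_abundance]
    fits: list[TrendFit] = []
    if gradient == "spatial":
        codes = meta.factor("compartment").map(SPATIAL_CODES)
        for phylum, row in by_phylum.iterrows():
            x = codes.reindex(row.index).to_numpy(float)
            fits.append(
                beta_regression_fit(
                    row.to_numpy(), x, "spatial", str(phylum), None, alpha
                )
            )
        return fits
    compartment = meta.factor("compartment")
    stage_codes = meta.factor("stage").map(TEMPORAL_CODES)
    for comp in pd.unique(compartment):
        samples = list(compartment.index[compartment == comp])
        for phylum, row in by_phylum[samples].iterrows():
            if row.sum() == 0:
                continue
            x = stage_codes.reindex(samples).to_numpy(float)
            fits.append(
                beta_regression_fit(
                    row.to_numpy(), x, "temporal", str(phylum), comp, alpha
                )
            )
    return fits


def trend_table(fits: list[TrendFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phylum": f.phylum,
                "gradient": f.gradient,
                "compartment": f.compartment,
                "slope": f.slope,
                "stderr": f.stderr,
                "z": f.z,
                "p_value": f.p_value,
                "precision": f.precision,
                "direction": f.direction,
                "n": f.n,
            }
            for f in fits
        ]
    )
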