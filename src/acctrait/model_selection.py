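"""Savage-Dickey Bayes factors and element ranking.

The null model pins ``beta2 = beta3 = 1`` (trait variance unlinked to the
substitution process).  Because the null is nested at the point
``(log beta2, log beta3) = (0, 0)`` and the priors are common across
elements, the Bayes factor in favour of the full model is the prior density
at the origin, ``1/(2 pi)`` for the two independent standard-normal priors,
divided by the posterior density at the origin, estimated by a bivariate
Gaussian kernel density over the MCMC draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

PRIOR_DENSITY_AT_ORIGIN = 1.0 / (2.0 * math.pi)


@dataclass
class ElementSummary:
    """Per-element fit summary used for ranking."""

    element_id: str
    bf: float
    median_log_beta_ratio: float
    ci80: tuple[float, float]
    rhat_max: float
    converged: bool
    n_samples: int

    def __post_init__(self) -> None:
        lo, hi = self.ci80
        if not (lo <= self.median_log_beta_ratio <= hi):
            raise ValueError("ci80 must bracket the median")
        if not self.bf > 0:
            raise ValueError("Bayes factor must be positive")


def savage_dickey_bf(
    log_beta2: np.ndarray,
    log_beta3: np.ndarray,
    bw_method: str | float = "scott",
    min_samples: int = 500,
) -> tuple[float, float, float]:
    """Bayes factor for the full model via the Savage-Dickey density ratio.

    Returns ``(bf, prior_density, posterior_density)`` where the densities
    are evaluated at ``(log beta2, log beta3) = (0, 0)``.
    """
    log_beta2 = np.asarray(log_beta2, dtype=float)
    log_beta3 = np.asarray(log_beta3, dtype=float)
    if log_beta2.shape != log_beta3.shape or log_beta2.ndim != 1:
        raise ValueError("log_beta2 and log_beta3 must be 1-D arrays of equal length")
    if len(log_beta2) < min_samples:
        raise ValueError(f"need at least {min_samples} posterior samples for a stable KDE")
    if np.std(log_beta2) == 0 or np.std(log_beta3) == 0:
        raise ValueError(
            "degenerate posterior samples (zero variance); run longer chains"
        )
    kde = gaussian_kde(np.vstack([log_beta2, log_beta3]), bw_method=bw_method)
    posterior = float(kde([[0.0], [0.0]])[0])
    if posterior <= 0:
        posterior = np.finfo(float).tiny
    return PRIOR_DENSITY_AT_ORIGIN / posterior, PRIOR_DENSITY_AT_ORIGIN, posterior


def categorize_evidence(bf: float) -> str:
    """Label the strength of evidence for the full model."""
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if bf >= 100:
        return "overwhelming"
    if bf >= 30:
        return "very strong"
    return "weak/none"


def rank_elements(
    summaries: list[ElementSummary],
    include_nonconverged: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank element summaries by descending Bayes factor.

    Non-converged elements are excluded from the main ranking and returned in
    a side table (set ``include_nonconverged`` to keep them in the ranking).
    Ties in BF break stably by element id.
    """
    if not summaries:
        raise ValueError("no summaries to rank")
    df = pd.DataFrame(
        {
            "element_id": [s.element_id for s in summaries],
            "bf": [s.bf for s in summaries],
            "label": [categorize_evidence(s.bf) for s in summaries],
            "median_log_beta_ratio": [s.median_log_beta_ratio for s in summaries],
            "q10": [s.ci80[0] for s in summaries],
            "q90": [s.ci80[1] for s in summaries],
            "rhat_max": [s.rhat_max for s in summaries],
            "converged": [s.converged for s in summaries],
            "n_samples": [s.n_samples for s in summaries],
        }
    )
    df = df.sort_values(
        ["bf", "element_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if include_nonconverged:
        return df, df.iloc[0:0]
    main = df[df["converged"]].reset_index(drop=True)
    side = df[~df["converged"]].reset_index(drop=True)
    return main, side
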