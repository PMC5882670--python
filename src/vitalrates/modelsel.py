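"""Shared model-selection utilities: AIC, delta-AIC ranking, generic fit results.

Every fitted model in the package (growth, survival, recruitment, size-at-age)
reports a :class:`FitResult` so rankings are comparable across modules.  Plain
AIC is used throughout (no small-sample AICc, no overdispersion adjustment);
candidates within ``EQUIVALENCE_DELTA`` = 2 AIC points are flagged as having
equal explanatory power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

EQUIVALENCE_DELTA = 2.0


def aic(loglik: float, npar: int) -> float:
    """Akaike information criterion, ``2*npar - 2*loglik``.

    Parameters
    ----------
    loglik : float
        Maximized log-likelihood. Must be finite.
    npar : int
        Number of estimated parameters, ``>= 0``.
    """
    if not math.isfinite(loglik):
        raise ValueError(f"loglik must be finite, got {loglik!r}")
    if npar < 0:
        raise ValueError(f"npar must be >= 0, got {npar}")
    return 2.0 * npar - 2.0 * loglik


@dataclass
class FitResult:
    """Generic estimation output shared across all fitted models.

    Attributes
    ----------
    label : str
        Human-readable model label, e.g. ``"phi(Cohort+Time) p(Time)"``.
    estimates : pandas.DataFrame
        One row per parameter: columns ``name``, ``value``, ``se``.
    loglik : float
        Maximized (marginal, where applicable) log-likelihood.
    npar : int
        Number of estimated parameters.
    status : str
        ``"ok"``, ``"boundary"``, ``"failed: <reason>"`` ...
    extra : dict
        Model-specific payload (fit object, predictions, diagnostics).
    """

    label: str
    estimates: pd.DataFrame
    loglik: float
    npar: int
    status: str = "ok"
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.npar)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"FitResult({self.label!r}, loglik={self.loglik:.3f}, "
            f"npar={self.npar}, aic={self.aic:.2f}, status={self.status!r})"
        )


def rank_by_aic(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fitted models by AIC.

    Failed fits (status starting with ``"failed"``) are listed at the bottom
    with missing AIC, never silently dropped.

    Returns a DataFrame with columns ``model``, ``npar``, ``loglik``, ``aic``,
    ``delta_aic``, ``equivalent`` (True when ``delta_aic < 2``), ``status``,
    sorted by AIC ascending.
    """
    if not fits:
        raise ValueError("need at least one candidate fit")
    rows = []
    for f in fits:
        failed = f.status.startswith("failed") or not math.isfinite(f.loglik)
        rows.append(
            {
                "model": f.label,
                "npar": f.npar,
                "loglik": f.loglik if not failed else float("nan"),
                "aic": f.aic if not failed else float("nan"),
                "status": f.status,
            }
        )
    tab = pd.DataFrame(rows)
    # parsimony tie-break: exact AIC ties go to the model with fewer parameters
    tab = tab.sort_values(["aic", "npar"], na_position="last", kind="mergesort").reset_index(drop=True)
    best = tab["aic"].min()
    tab["delta_aic"] = tab["aic"] - best
    tab["equivalent"] = tab["delta_aic"] < EQUIVALENCE_DELTA
    return tab[["model", "npar", "loglik", "aic", "delta_aic", "equivalent", "status"]]
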