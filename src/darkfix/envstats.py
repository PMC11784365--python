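"""Environmental covariates and gradient correlation analysis.

Covers the three wet-lab derived quantities and the rank-correlation
analysis used to relate them to gene/transcript abundance:

* loss-on-ignition organic matter (LOI), with both the conventional
  mass-loss form and the printed residue-ratio form available;
* porewater anion concentrations back-calculated from a 1:10
  soil:water extract using the fresh/dry weight difference as native
  porewater volume;
* Spearman's rank correlation (Pearson on mid-ranks) with a two-sided
  t-approximation p-value, or exact permutation p for small n.

The spatial design is encoded ordinally: distance to sea counts
marine=1, brackish=2, fresh=3; surface elevation pioneer=1, low=2,
high=3; soil depth surface=0, deep=1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .types import COVARIATE_ORDER, metadata_frame

GRADIENT_ORDINALS = ("distance_to_sea", "surface_elevation", "soil_depth")


def compute_loi(dw_before: float, dw_after: float, formula: str = "loss") -> float:
    """Organic matter percent from dry weights before/after ignition.

    ``loss`` (default) returns the mass lost on ignition,
    (before - after) / before * 100 — the conventional loss-on-ignition
    organic-matter estimate.  ``as_printed`` returns the residue ratio
    after / before * 100 instead.
    """
    if formula not in ("loss", "as_printed"):
        raise ValidationError(f"unknown LOI formula {formula!r}")
    if dw_before <= 0:
        raise ValidationError("dry weight before ignition must be positive")
    if dw_after > dw_before:
        raise ValidationError("mass gain on ignition is impossible")
    if dw_after <= 0:
        raise ValidationError("dry weight after ignition must be positive")
    if formula == "loss":
        return (dw_before - dw_after) / dw_before * 100.0
    return dw_after / dw_before * 100.0


def porewater_concentration(
    extract_conc: float,
    soil_fresh: float,
    soil_dry: float,
    water_ratio: float = 10.0,
) -> float:
    """Back-calculate a porewater concentration from a soil:water extract.

    The native porewater volume w (mL) is taken as fresh minus dry soil mass
    (water density 1 g/mL).  The extract dilutes that porewater into
    ``water_ratio x soil_fresh + w`` mL total, so the porewater concentration
    is ``extract_conc * (water_ratio * soil_fresh + w) / w``.
    """
    w = soil_fresh - soil_dry
    if w <= 0:
        raise ValidationError("no native porewater: fresh weight <= dry weight")
    return extract_conc * (water_ratio * soil_fresh + w) / w


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    significant: bool


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(
    x,
    y,
    alpha: float = 0.05,
    x_name: str = "x",
    y_name: str = "y",
    method: str = "auto",
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (average ranks on ties).  The
    p-value uses the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2
    degrees of freedom; with ``method="exact"`` (or automatically when
    n <= 8) it is the exact two-sided permutation p over all n! orderings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 observations")
    rx, ry = _midranks(x), _midranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValidationError("undefined correlation: constant vector after ranking")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "auto":
        method = "exact" if n <= 8 else "t"
    if method == "exact":
        count = 0
        total = 0
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValidationError(f"unknown p-value method {method!r}")
    p = min(p, 1.0)
    return CorrelationResult(
        x_name=x_name, y_name=y_name, rho=rho, p_value=p, n=n,
        significant=p < alpha,
    )


def correlation_table(
    metadata: Iterable,
    targets: pd.DataFrame,
    alpha: float = 0.05,
    covariates=COVARIATE_ORDER,
    bh_correct: bool = False,
    method: str = "t",
) -> pd.DataFrame:
    """Cross every target column against the environmental covariates.

    ``metadata`` is a list of SampleMetadata (or an already-tabulated frame
    from :func:`darkfix.types.metadata_frame`); ``targets`` has samples as
    index (e.g. per-cell transcript copies of the starred key genes).  Rows of
    the result are targets, columns covariates; cells hold (rho, p,
    significant).  Per-test significance at ``alpha`` with no multiplicity
    correction by default; ``bh_correct=True`` switches to
    Benjamini-Hochberg-adjusted significance.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    common = [s for s in targets.index if s in meta.index]
    if not common:
        raise ValidationError("no overlapping samples between metadata and targets")
    meta = meta.loc[common]
    targets = targets.loc[common]
    rows = []
    for target in targets.columns:
        for cov in covariates:
            r = spearman(
                targets[target].to_numpy(), meta[cov].to_numpy(),
                alpha=alpha, x_name=target, y_name=cov, method=method,
            )
            rows.append(
                {
                    "target": target, "covariate": cov, "rho": r.rho,
                    "p_value": r.p_value, "n": r.n, "significant": r.significant,
                }
            )
    tab = pd.DataFrame(rows)
    if bh_correct:
        tab = tab.sort_values("p_value", kind="stable").reset_index(drop=True)
        m = len(tab)
        ranks = np.arange(1, m + 1)
        q = np.minimum.accumulate((tab["p_value"].to_numpy() * m / ranks)[::-1])[::-1]
        tab["significant"] = q < alpha
    tab["covariate"] = pd.Categorical(tab["covariate"], categories=list(covariates), ordered=True)
    return tab.sort_values(["target", "covariate"]).reset_index(drop=True)


def gradient_correlations(metadata, alpha: float = 0.05, method: str = "t") -> pd.DataFrame:
    """Covariates against the three spatial gradient ordinals.

    Rows are the gradients (distance to sea, surface elevation, soil depth),
    columns the eight covariates in the standard reporting order.
    """
    meta = metadata if isinstance(metadata, pd.DataFrame) else metadata_frame(metadata)
    rows = []
    for grad in GRADIENT_ORDINALS:
        for cov in COVARIATE_ORDER:
            r = spearman(
                meta[cov].to_numpy(), meta[grad].to_numpy(),
                alpha=alpha, x_name=cov, y_name=grad, method=method,
            )
            rows.append(
                {
                    "gradient": grad, "covariate": cov, "rho": r.rho,
                    "p_value": r.p_value, "n": r.n, "significant": r.significant,
                }
            )
    return pd.DataFrame(rows)


def pivot_correlations(tab: pd.DataFrame, row_key: str = "target") -> pd.DataFrame:
    """Wide rho table (rows x covariates), significant entries starred."""
    def cell(row):
        mark = "*" if row["significant"] else ""
        return f"{row['rho']:.2f}{mark}"

    tab = tab.copy()
    tab["cell"] = tab.apply(cell, axis=1)
    col = "covariate" if "covariate" in tab.columns else "gradient"
    wide = tab.pivot(index=row_key, columns=col, values="cell")
    order = [c for c in COVARIATE_ORDER if c in wide.columns]
    return wide[order]
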