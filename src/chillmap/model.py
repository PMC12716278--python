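"""Logistic time-temperature chill-injury survival model.

The survival of a cohort exposed for ``t`` hours at temperature ``T`` (degC)
is modelled on the logit scale as

    logit S(t, T) = a + b * t * (T - c)

where ``c`` is the upper limit of the chill injury zone (ULCIZ): the warmest
temperature at which chill injury accumulates.  Below ``c`` the term
``t * (T - c)`` is a (negative) degree-hour dose, so survival declines with
both exposure time and depth of cold.  The ratio ``a / b`` is the sum of
injurious temperatures (SIT): the degree-hour budget that halves survival,
equivalently the time to 50% survival one degree below the ULCIZ.

Parameters are estimated from survival assays (temperature x exposure-time
factorials) by nonlinear least squares with a deterministic multi-start grid,
since the objective is non-convex in ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

__all__ = [
    "ChillParams",
    "SurvivalAssay",
    "ChillInjuryModel",
    "ChillInjuryResults",
    "survival",
    "fit_chill_model",
    "sit",
    "lt50_time",
    "FitError",
]

#: logit bound used everywhere; expit saturates far earlier so this only
#: protects the exp() inside diagnostics from overflow.
_LOGIT_CAP = 700.0


class FitError(RuntimeError):
    """Raised when the nonlinear least-squares fit cannot be completed."""


@dataclass(frozen=True)
class ChillParams:
    """Fitted chill-injury parameters for one species.

    Attributes
    ----------
    a : float
        Dimensionless logit intercept; survival with no cold exposure is
        ``expit(a)``.
    b : float
        Injury rate per degree-hour (1 / (h * degC)); must be positive.
    c : float
        ULCIZ in degC: the warmest temperature at which injury accrues.
    se_a, se_b, se_c : float, optional
        Asymptotic standard errors from the fit (NaN when unknown).
    species_label : str
        Free-text label carried through outputs.
    """

    a: float
    b: float
    c: float
    se_a: float = math.nan
    se_b: float = math.nan
    se_c: float = math.nan
    species_label: str = ""

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")
        if self.b <= 0:
            raise ValueError("injury rate b must be > 0")
        for name in ("se_a", "se_b", "se_c"):
            v = getattr(self, name)
            if math.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def ulciz(self) -> float:
        """Upper limit of the chill injury zone, degC."""
        return self.c

    @property
    def sit(self) -> float:
        """Sum of injurious temperatures (degree-hours), ``a / b``."""
        return sit(self)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "se_c": self.se_c,
            "species_label": self.species_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChillParams":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass(frozen=True)
class SurvivalAssay:
    """One treatment cell of a chill-tolerance assay."""

    temperature: float  # degC
    exposure: float  # hours
    n_exposed: int
    n_dead: float

    def __post_init__(self) -> None:
        if self.exposure < 0:
            raise ValueError("exposure must be >= 0")
        if self.n_exposed < 1:
            raise ValueError("n_exposed must be >= 1")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError("n_dead must lie in [0, n_exposed]")

    @property
    def proportion_dead(self) -> float:
        return self.n_dead / self.n_exposed

    @property
    def proportion_alive(self) -> float:
        return 1.0 - self.proportion_dead


def survival(t, T, p: ChillParams):
    """Predicted survival after ``t`` hours at ``T`` degC.

    Evaluated on the logit scale so that extreme doses saturate to 0/1
    without overflow.  Accepts scalars or arrays (broadcast together).
    """
    t = np.asarray(t, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite time or temperature")
    if np.any(t < 0):
        raise ValueError("exposure time must be >= 0")
    eta = np.clip(p.a + p.b * t * (T - p.c), -_LOGIT_CAP, _LOGIT_CAP)
    # keep the result in the open interval: expit rounds to exactly 1.0
    # once eta exceeds ~37, which would break downstream logits
    out = np.clip(expit(eta), 5e-324, np.nextafter(1.0, 0.0))
    return float(out) if out.ndim == 0 else out


def sit(p: ChillParams) -> float:
    """Sum of injurious temperatures, ``a / b`` (degree-hours).

    Equals the exposure time to 50% survival one degree below the ULCIZ,
    ``-a / (b * (T - c))`` at ``T = c - 1``.
    """
    if p.b <= 0:
        raise ValueError("injury rate b must be > 0")
    return p.a / p.b


def lt50_time(T: float, p: ChillParams) -> float:
    """Exposure time (h) at which survival falls to 0.5 at temperature ``T``.

    Defined only below the ULCIZ; solves ``a + b * t * (T - c) = 0``.
    """
    if not math.isfinite(T):
        raise ValueError("temperature must be finite")
    if T >= p.c:
        raise ValueError(
            f"no chill injury at {T} degC: at or above the ULCIZ ({p.c} degC)"
        )
    return -p.a / (p.b * (T - p.c))


# ---------------------------------------------------------------------------
# fitting


def _as_assays(data) -> list[SurvivalAssay]:
    if isinstance(data, pd.DataFrame):
        rows = []
        for r in data.itertuples(index=False):
            n = int(getattr(r, "n_exposed"))
            if hasattr(r, "n_dead") and not pd.isna(getattr(r, "n_dead", np.nan)):
                dead = float(r.n_dead)
            else:
                dead = float(r.proportion_dead) * n
            rows.append(
                SurvivalAssay(
                    temperature=float(r.temperature_c),
                    exposure=float(r.exposure_h),
                    n_exposed=n,
                    n_dead=dead,
                )
            )
        return rows
    return list(data)


def _validate_design(assays: Sequence[SurvivalAssay]) -> None:
    if len(assays) < 4:
        raise ValueError("need at least 4 assay cells")
    temps = {a.temperature for a in assays}
    times = {a.exposure for a in assays}
    if len(temps) < 2 or len(times) < 2:
        raise ValueError("design must span >= 2 temperatures and >= 2 exposure times")
    props = [a.proportion_dead for a in assays]
    if all(p == 0 for p in props):
        raise FitError("degenerate data: no cell shows any injury (all alive)")
    if all(p == 1 for p in props):
        raise FitError("degenerate data: every cell is all-dead")


class ChillInjuryModel:
    """Nonlinear least-squares model for a time-temperature survival surface.

    Parameters
    ----------
    assays : sequence of SurvivalAssay or DataFrame
        DataFrames need columns ``temperature_c, exposure_h, n_exposed`` and
        either ``n_dead`` or ``proportion_dead`` (mortality, as assay tables
        are conventionally printed; converted to survival at ingest).
    weighting : {"cells", "counts"}
        "cells" fits each cell mean with equal weight (for a balanced design
        this equals replicate-level least squares); "counts" weights each
        cell by ``n_exposed``.
    species_label : str
    """

    def __init__(self, assays, weighting: str = "counts", species_label: str = ""):
        if weighting not in ("cells", "counts"):
            raise ValueError("weighting must be 'cells' or 'counts'")
        self.assays = _as_assays(assays)
        _validate_design(self.assays)
        self.weighting = weighting
        self.species_label = species_label
        self._t = np.array([a.exposure for a in self.assays])
        self._T = np.array([a.temperature for a in self.assays])
        self._n = np.array([a.n_exposed for a in self.assays], dtype=float)
        self._s = np.array([a.proportion_alive for a in self.assays])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "ChillInjuryModel":
        label = kw.pop("species_label", None)
        if label is None and "species" in df.columns and len(df):
            label = str(df["species"].iloc[0])
        return cls(df, species_label=label or "", **kw)

    # -- internals ---------------------------------------------------------

    def _weights(self) -> np.ndarray:
        if self.weighting == "counts":
            return np.sqrt(self._n / self._n.mean())
        return np.ones_like(self._s)

    def _residuals(self, theta: np.ndarray, w: np.ndarray) -> np.ndarray:
        a, b, c = theta
        eta = np.clip(a + b * self._t * (self._T - c), -_LOGIT_CAP, _LOGIT_CAP)
        return w * (expit(eta) - self._s)

    def _start_grid(self) -> list[tuple[float, float, float]]:
        # deterministic multi-start: c over the observed temperature range
        # (+10 degC headroom, 2 degC step), a from the logit of the
        # best-condition survival, b over decades.
        s_best = float(np.clip(self._s.max(), 1e-3, 1 - 1e-3))
        a0 = float(logit(s_best))
        c_grid = np.arange(self._T.min(), self._T.max() + 10.0 + 1e-9, 2.0)
        b_grid = (1e-4, 1e-3, 1e-2, 1e-1)
        return [(a0, b0, c0) for c0 in c_grid for b0 in b_grid]

    def fit(self) -> "ChillInjuryResults":
        """Fit by multi-start nonlinear least squares.

        Returns the start with the smallest weighted SSE; exact SSE ties are
        broken toward smaller ``|b|``.  Raises :class:`FitError` if no start
        converges to a valid (b > 0) optimum.
        """
        w = self._weights()
        best = None
        best_sse = math.inf
        for a0, b0, c0 in self._start_grid():
            try:
                sol = least_squares(
                    self._residuals, x0=[a0, b0, c0], args=(w,),
                    method="lm", max_nfev=20000,
                )
            except Exception:
                continue
            sse = float(np.sum(sol.fun**2))
            if sol.x[1] <= 0:
                continue
            better = sse < best_sse - 1e-12
            tie = abs(sse - best_sse) <= 1e-12 and best is not None and abs(
                sol.x[1]
            ) < abs(best.x[1])
            if better or tie:
                best, best_sse = sol, sse
        if best is None:
            raise FitError(
                "no start converged; best residual sum of squares seen: "
                f"{best_sse:.6g}"
            )
        se = self._asymptotic_se(best)
        params = ChillParams(
            a=float(best.x[0]), b=float(best.x[1]), c=float(best.x[2]),
            se_a=se[0], se_b=se[1], se_c=se[2],
            species_label=self.species_label,
        )
        return ChillInjuryResults(self, params, sse=best_sse)

    def _asymptotic_se(self, sol) -> np.ndarray:
        n, k = len(self._s), 3
        dof = max(n - k, 1)
        sigma2 = float(np.sum(sol.fun**2)) / dof
        try:
            JTJ = sol.jac.T @ sol.jac
            cov = sigma2 * np.linalg.inv(JTJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
        return se


class ChillInjuryResults:
    """Fitted chill-injury surface: parameter estimates and derived metrics."""

    def __init__(self, model: ChillInjuryModel, params: ChillParams, sse: float):
        self.model = model
        self.params = params
        self.sse = sse

    @property
    def ulciz(self) -> float:
        return self.params.c

    @property
    def sit(self) -> float:
        return self.params.sit

    def predict(self, t, T):
        """Predicted survival at exposure ``t`` (h) and temperature ``T``."""
        return survival(t, T, self.params)

    def lt50_time(self, T: float) -> float:
        return lt50_time(T, self.params)

    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model._t, self.model._T)

    def resid(self) -> np.ndarray:
        return self.model._s - self.fittedvalues()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Chill-injury survival model (nonlinear least squares)",
            "=" * 56,
            f"species:    {p.species_label or '<unlabelled>'}",
            f"cells:      {len(self.model.assays)}   weighting: {self.model.weighting}",
            f"SSE:        {self.sse:.6g}",
            "-" * 56,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
            f"{'a':<8}{p.a:>14.4f}{p.se_a:>14.4f}",
            f"{'b':<8}{p.b:>14.6f}{p.se_b:>14.6f}",
            f"{'c (ULCIZ)':<8}{p.c:>13.4f}{p.se_c:>14.4f}",
            "-" * 56,
            f"ULCIZ: {p.c:.3f} degC    SIT (a/b): {p.sit:.2f} degree-hours",
        ]
        return "\n".join(lines)

    def plot_surface(self, t_max: float | None = None, ax=None):
        """Contour plot of the fitted survival surface (time x temperature)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        tmax = t_max or float(m._t.max())
        tt = np.linspace(0, tmax, 120)
        TT = np.linspace(m._T.min() - 1, max(m._T.max(), self.params.c) + 1, 120)
        G_t, G_T = np.meshgrid(tt, TT)
        S = self.predict(G_t, G_T)
        cs = ax.contourf(G_t, G_T, S, levels=np.linspace(0, 1, 11), cmap="viridis")
        ax.axhline(self.params.c, color="w", ls="--", lw=1)
        ax.set_xlabel("exposure time (h)")
        ax.set_ylabel("temperature (degC)")
        ax.figure.colorbar(cs, ax=ax, label="survival")
        return ax


def fit_chill_model(
    assays: Iterable[SurvivalAssay] | pd.DataFrame,
    weighting: str = "counts",
    species_label: str = "",
) -> ChillParams:
    """Convenience wrapper: fit and return the :class:`ChillParams` triple."""
    model = ChillInjuryModel(assays, weighting=weighting, species_label=species_label)
    return model.fit().params
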