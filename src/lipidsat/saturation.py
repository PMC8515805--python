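"""One-site saturation fitting, apparent free energies, and convergence scans.

Site occupancy (percent) versus free-ligand concentration (percent) is fit
to the one-site specific-binding isotherm

    y = Bmax * x / (Kd + x)

by unconstrained nonlinear least squares, yielding the apparent dissociation
constant Kd^app and plateau Bmax^app. Replicate scatter is summarised as the
standard error of the mean of per-replicate fits. Apparent free-energy
differences between sites follow from RT ln(Kd_A / Kd_B).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from lipidsat.constants import GAS_CONSTANT_KJ
from lipidsat.system import SimulationCondition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaturationPoint:
    """One (free-ligand %, site occupancy %) observation."""

    x: float
    y: float
    condition: SimulationCondition

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("free-ligand concentration must be >= 0")
        if not 0.0 <= self.y <= 100.0:
            raise ValueError("occupancy must lie in [0, 100] percent")


@dataclass
class FitResult:
    """Fitted one-site isotherm parameters with uncertainty metadata.

    ``kd_stderr`` is the SEM over per-replicate Kd fits (nan when fewer than
    two replicate fits are available); ``fit_stderrs`` are the asymptotic
    standard errors (bmax, kd) of this fit itself.
    """

    kd_app: float
    bmax_app: float
    converged: bool
    residual_norm: float = math.nan
    fit_stderrs: tuple[float, float] = (math.nan, math.nan)
    kd_stderr: float = math.nan
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.converged and (self.kd_app <= 0 or self.bmax_app <= 0):
            raise ValueError("a converged fit requires positive Kd and Bmax")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return one_site_isotherm(np.asarray(x, dtype=float), self.bmax_app, self.kd_app)

    def to_dict(self) -> dict:
        return {
            "kd_app": self.kd_app,
            "bmax_app": self.bmax_app,
            "converged": self.converged,
            "residual_norm": self.residual_norm,
            "fit_stderrs": list(self.fit_stderrs),
            "kd_stderr": self.kd_stderr,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class FreeEnergyResult:
    """Apparent free energies derived from fitted Kd values (kJ/mol)."""

    delta_g_app: float
    temperature: float
    delta_delta_g_app: float = math.nan
    gas_constant: float = GAS_CONSTANT_KJ


def one_site_isotherm(x: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Specific one-site binding: y = bmax * x / (kd + x)."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def _as_xy(points: Sequence[SaturationPoint] | tuple) -> tuple[np.ndarray, np.ndarray]:
    if len(points) and isinstance(points[0], SaturationPoint):
        x = np.array([p.x for p in points], dtype=float)
        y = np.array([p.y for p in points], dtype=float)
    else:
        x, y = points  # (x_array, y_array) convenience form
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    return x, y


def fit_one_site(points: Sequence[SaturationPoint]) -> FitResult:
    """Unconstrained least-squares fit of the one-site isotherm.

    Requires at least three distinct x values. Degenerate data (all-zero
    occupancies) or optimizer failure is flagged via ``converged=False``
    rather than raised.
    """
    x, y = _as_xy(points)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct free-ligand concentrations to fit")

    if np.allclose(y, 0.0):
        logger.warning("all occupancies are zero; Kd is unidentifiable")
        return FitResult(
            kd_app=math.nan,
            bmax_app=0.0,
            converged=False,
            residual_norm=0.0,
            n_points=x.size,
        )

    p0 = (float(np.max(y)), float(np.median(x)))
    try:
        popt, pcov = curve_fit(
            one_site_isotherm,
            x,
            y,
            p0=p0,
            maxfev=10_000,
            xtol=1e-8,
            ftol=1e-8,
        )
    except RuntimeError as err:
        logger.warning("one-site fit failed to converge: %s", err)
        return FitResult(
            kd_app=math.nan,
            bmax_app=math.nan,
            converged=False,
            n_points=x.size,
        )
    bmax, kd = (float(v) for v in popt)
    residual = float(np.linalg.norm(y - one_site_isotherm(x, bmax, kd)))
    stderrs = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    converged = kd > 0 and bmax > 0 and np.all(np.isfinite(popt))
    if not converged:
        logger.warning(
            "one-site fit returned non-physical parameters: Kd=%.4g Bmax=%.4g",
            kd,
            bmax,
        )
        return FitResult(
            kd_app=kd,
            bmax_app=bmax,
            converged=False,
            residual_norm=residual,
            n_points=x.size,
        )
    return FitResult(
        kd_app=kd,
        bmax_app=bmax,
        converged=True,
        residual_norm=residual,
        fit_stderrs=stderrs,
        kd_stderr=math.nan,
        n_points=x.size,
    )


def replicate_sem(values: Iterable[float]) -> float:
    """Standard error of the mean: sample standard deviation / sqrt(n)."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("SEM needs at least two values")
    return float(np.std(values, ddof=1) / math.sqrt(values.size))


def fit_replicates(points: Sequence[SaturationPoint]) -> FitResult:
    """Pooled fit with the headline Kd error taken across replicate fits.

    All points enter one pooled fit (reported parameters); additionally each
    replicate's own points are fit and the SEM of the per-replicate Kd
    estimates populates ``kd_stderr``. Replicates whose individual fit fails
    or that have too few concentrations are skipped for the SEM.
    """
    pooled = fit_one_site(points)
    by_replicate: dict[int, list[SaturationPoint]] = {}
    for p in points:
        by_replicate.setdefault(p.condition.replicate_id, []).append(p)
    kds = []
    for rep, rep_points in sorted(by_replicate.items()):
        try:
            rep_fit = fit_one_site(rep_points)
        except ValueError:
            continue
        if rep_fit.converged:
            kds.append(rep_fit.kd_app)
    if len(kds) >= 2:
        pooled.kd_stderr = replicate_sem(kds)
    return pooled


def delta_g_apparent(
    kd_percent: float, temperature: float, gas_constant: float = GAS_CONSTANT_KJ
) -> float:
    """Apparent binding free energy RT ln(Kd) with Kd as a mole fraction.

    Negative for sub-unity mole-fraction Kd (i.e. any binding stronger than
    the reference state), so that dG_A - dG_B equals
    :func:`delta_delta_g`. The absolute value depends on the percent/100
    reference-state choice — only differences between sites are
    reference-free.
    """
    if kd_percent <= 0:
        raise ValueError("Kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return gas_constant * temperature * math.log(kd_percent / 100.0)


def delta_delta_g(
    kd_a: float,
    kd_b: float,
    temperature: float,
    gas_constant: float = GAS_CONSTANT_KJ,
) -> float:
    """Apparent free-energy difference between two sites, RT ln(Kd_A/Kd_B).

    Equals dG_A - dG_B with dG = -RT ln Kd; the Kd units cancel, so any
    common unit may be used. Negative values mean site A binds more strongly.
    """
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("Kd values must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return gas_constant * temperature * math.log(kd_a / kd_b)


@dataclass
class SaturationDataset:
    """Per-(condition, replicate) bound-state series for one site.

    Each entry couples the free-ligand abscissa ``x`` with the raw
    per-residue boolean contact matrix, so occupancies can be recomputed
    under frame truncation for convergence analysis.
    """

    entries: list["DatasetEntry"] = field(default_factory=list)
    site_id: str = "site"

    def add(
        self,
        x: float,
        residue_states: np.ndarray,
        condition: SimulationCondition,
    ) -> None:
        self.entries.append(DatasetEntry(x, np.asarray(residue_states, bool), condition))

    @property
    def replicate_ids(self) -> list[int]:
        return sorted({e.condition.replicate_id for e in self.entries})

    def points(
        self,
        replicates: Sequence[int] | None = None,
        max_frames: int | None = None,
    ) -> list[SaturationPoint]:
        """Saturation points, optionally restricted to replicates/frames."""
        selected = []
        for entry in self.entries:
            if replicates is not None and entry.condition.replicate_id not in replicates:
                continue
            states = entry.residue_states
            if max_frames is not None:
                states = states[:, :max_frames]
            occ = 100.0 * float(states.mean())
            selected.append(SaturationPoint(entry.x, occ, entry.condition))
        return selected


@dataclass
class DatasetEntry:
    x: float
    residue_states: np.ndarray  # (n_residues, n_frames) bool
    condition: SimulationCondition


def convergence_scan(
    dataset: SaturationDataset,
    replicate_subsets: Sequence[Sequence[int]] | None = None,
    frame_truncations: Sequence[int] | None = None,
):
    """Re-fit Kd on replicate subsets and/or truncated windows.

    Returns a pandas DataFrame with one row per (subset, truncation)
    combination, reporting the fitted Kd/Bmax and the relative drift of Kd
    from the full-data fit. ``None`` for either axis means "use everything".
    """
    import pandas as pd

    if replicate_subsets is not None and len(replicate_subsets) == 0:
        raise ValueError("replicate_subsets must not be empty when given")
    if dataset.replicate_ids and len(dataset.replicate_ids) < 2:
        raise ValueError("convergence scan needs >= 2 replicates")

    full = fit_one_site(dataset.points())
    subsets: list[tuple[int, ...] | None] = (
        [tuple(s) for s in replicate_subsets] if replicate_subsets else [None]
    )
    truncations: list[int | None] = (
        list(frame_truncations) if frame_truncations else [None]
    )

    rows = []
    for subset, max_frames in itertools.product(subsets, truncations):
        fit = fit_one_site(dataset.points(replicates=subset, max_frames=max_frames))
        drift = (
            (fit.kd_app - full.kd_app) / full.kd_app
            if fit.converged and full.converged
            else math.nan
        )
        rows.append(
            {
                "replicates": "all" if subset is None else ",".join(map(str, subset)),
                "max_frames": -1 if max_frames is None else max_frames,
                "kd_app": fit.kd_app,
                "bmax_app": fit.bmax_app,
                "converged": fit.converged,
                "kd_relative_drift": drift,
            }
        )
    return pd.DataFrame(rows)


def all_pairs_delta_delta_g(
    kd_by_site: dict[str, float], temperature: float
):
    """Table of RT ln(Kd_A/Kd_B) for every ordered site pair."""
    import pandas as pd

    rows = [
        {
            "site_a": a,
            "site_b": b,
            "delta_delta_g_kj_mol": delta_delta_g(kd_by_site[a], kd_by_site[b], temperature),
        }
        for a in kd_by_site
        for b in kd_by_site
        if a != b
    ]
    return pd.DataFrame(rows)
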