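"""Two-component semisupervised kernel-density mixture models.

For each biomarker the module fits a nonparametric mixture of a "normal"
component P(x|not-E) and an "abnormal" component P(x|E) over score
residuals.  The components are initialized from the young-adult (normal)
and older-adult (abnormal) group labels as separate Gaussian kernel density
estimates, then refined by alternating soft-responsibility / weighted-refit
steps.  YA rows stay anchored in the normal component (they are the assumed
pre-decline controls); OA rows, a latent blend of participants before and
after the event, are re-weighted between components, so the final split
reflects the data rather than the age labels alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .battery import DECREASING, INCREASING
from .exceptions import ConfigurationError, DegenerateDataError, DirectionViolationError

_DENSITY_FLOOR = 1e-12
_GRID_SIZE = 512
_GRID_PAD_BW = 4.0  # grid extends this many bandwidths past the data span


def _silverman_bandwidth(x: np.ndarray, w: np.ndarray, span: float) -> float:
    """Rule-of-thumb bandwidth from the weighted standard deviation.

    Uses the effective sample size (sum w)^2 / sum w^2 and floors the result
    at a small fraction of the data span so near-degenerate components
    (e.g. a floor-effect spike) keep a usable smoother.
    """
    wsum = w.sum()
    if wsum <= 0:
        raise DegenerateDataError("component has zero total weight")
    wn = w / wsum
    mu = float(wn @ x)
    var = float(wn @ (x - mu) ** 2)
    neff = wsum**2 / float((w**2).sum())
    bw = 0.9 * math.sqrt(var) * neff ** (-0.2)
    floor = max(1e-3 * span, 1e-9)
    return max(bw, floor)


def _kde(x: np.ndarray, w: np.ndarray, bw: float, at: np.ndarray) -> np.ndarray:
    """Weighted Gaussian KDE evaluated at ``at`` (weights need not sum to 1)."""
    wn = w / w.sum()
    z = (at[:, None] - x[None, :]) / bw
    k = np.exp(-0.5 * z * z) / (bw * math.sqrt(2.0 * math.pi))
    return k @ wn


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cutoff = 0.5 * w.sum()
    return float(x[order][int(np.searchsorted(cw, cutoff))])


@dataclass
class MixtureFit:
    """Fitted two-component mixture for a single biomarker.

    Densities are stored on a shared evaluation grid; :func:`event_probabilities`
    interpolates on that grid, so a fit serialized with :meth:`to_text` and
    reloaded evaluates identically.
    """

    biomarker: str
    direction: str
    grid: np.ndarray
    event_density: np.ndarray      # P(x | E): abnormal component
    nonevent_density: np.ndarray   # P(x | not-E): normal component
    mixture_weight: float          # abnormal-component proportion
    bandwidths: tuple[float, float]  # (event, nonevent)
    n_iter: int = 0
    converged: bool = True

    def to_text(self, path: str | Path) -> None:
        lines = [
            f"# biomarker\t{self.biomarker}",
            f"# direction\t{self.direction}",
            f"# mixture_weight\t{float(self.mixture_weight)!r}",
            f"# bandwidth_event\t{float(self.bandwidths[0])!r}",
            f"# bandwidth_nonevent\t{float(self.bandwidths[1])!r}",
            f"# n_iter\t{self.n_iter}",
            f"# converged\t{self.converged}",
            "grid\tevent_density\tnonevent_density",
        ]
        for g, e, ne in zip(self.grid, self.event_density, self.nonevent_density):
            lines.append(f"{float(g)!r}\t{float(e)!r}\t{float(ne)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "MixtureFit":
        meta: dict[str, str] = {}
        rows: list[tuple[float, float, float]] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                key, value = line[1:].strip().split("\t")
                meta[key] = value
            elif line and not line.startswith("grid"):
                g, e, ne = line.split("\t")
                rows.append((float(g), float(e), float(ne)))
        arr = np.array(rows, dtype=float)
        return cls(
            biomarker=meta["biomarker"],
            direction=meta["direction"],
            grid=arr[:, 0],
            event_density=arr[:, 1],
            nonevent_density=arr[:, 2],
            mixture_weight=float(meta["mixture_weight"]),
            bandwidths=(
                float(meta["bandwidth_event"]),
                float(meta["bandwidth_nonevent"]),
            ),
            n_iter=int(meta["n_iter"]),
            converged=meta["converged"] == "True",
        )


def fit_mixture(
    values: Sequence[float],
    group_labels: Sequence[str],
    direction: str,
    biomarker: str = "",
    *,
    min_group: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
    hard_assignment: bool = False,
    check_direction: bool = True,
    direction_tol_sd: float = 0.05,
    grid_size: int = _GRID_SIZE,
) -> MixtureFit:
    """Fit the semisupervised two-component KDE mixture for one biomarker.

    Parameters
    ----------
    values, group_labels
        Non-missing score residuals and their "YA"/"OA" group labels.
    direction
        Decline direction of the biomarker; the fitted abnormal component
        must sit on this side of the normal component.
    hard_assignment
        Use 0/1 responsibilities instead of soft weights during refinement.
    check_direction
        Raise :class:`DirectionViolationError` when the abnormal component's
        median lies on the wrong side of the normal component's median by
        more than ``direction_tol_sd`` pooled standard deviations.
    """
    if direction not in (DECREASING, INCREASING):
        raise ConfigurationError(f"unknown decline direction {direction!r}")
    x = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    keep = ~np.isnan(x)
    x, labels = x[keep], labels[keep]
    n_ya = int((labels == "YA").sum())
    n_oa = int((labels == "OA").sum())
    if n_ya < min_group or n_oa < min_group:
        raise DegenerateDataError(
            f"{biomarker or 'biomarker'}: need >= {min_group} values per group "
            f"(got YA={n_ya}, OA={n_oa})"
        )
    span = float(x.max() - x.min())
    if span <= 0:
        raise DegenerateDataError(f"{biomarker or 'biomarker'}: all values identical")

    # responsibilities = probability of belonging to the abnormal component.
    # YA rows are the assumed pre-decline controls: they stay anchored in the
    # normal component, which keeps the refinement from collapsing; only OA
    # rows (a latent pre/post mixture) get re-weighted between components.
    is_oa = labels == "OA"
    resp = is_oa.astype(float)
    n_iter = 0
    converged = False
    bw_e = bw_ne = span / 10.0
    for n_iter in range(1, max_iter + 1):
        w_e = np.clip(resp, 1e-6, None)
        w_ne = np.clip(1.0 - resp, 1e-6, None)
        bw_e = _silverman_bandwidth(x, w_e, span)
        bw_ne = _silverman_bandwidth(x, w_ne, span)
        f_e = np.clip(_kde(x, w_e, bw_e, x), _DENSITY_FLOOR, None)
        f_ne = np.clip(_kde(x, w_ne, bw_ne, x), _DENSITY_FLOOR, None)
        weight = float(resp.mean())
        post = weight * f_e / (weight * f_e + (1.0 - weight) * f_ne)
        if hard_assignment:
            post = (post > 0.5).astype(float)
        post = np.where(is_oa, post, 0.0)
        delta = float(np.abs(post - resp).mean())
        resp = post
        if delta < tol:
            converged = True
            break

    weight = float(resp.mean())
    w_e = np.clip(resp, 1e-6, None)
    w_ne = np.clip(1.0 - resp, 1e-6, None)
    bw_e = _silverman_bandwidth(x, w_e, span)
    bw_ne = _silverman_bandwidth(x, w_ne, span)
    pad = _GRID_PAD_BW * max(bw_e, bw_ne)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    fit = MixtureFit(
        biomarker=biomarker,
        direction=direction,
        grid=grid,
        event_density=_kde(x, w_e, bw_e, grid),
        nonevent_density=_kde(x, w_ne, bw_ne, grid),
        mixture_weight=weight,
        bandwidths=(float(bw_e), float(bw_ne)),
        n_iter=n_iter,
        converged=converged,
    )

    if check_direction:
        med_e = _weighted_median(x, w_e)
        med_ne = _weighted_median(x, w_ne)
        pooled_sd = float(x.std())
        gap = med_e - med_ne
        wrong = gap > 0 if direction == DECREASING else gap < 0
        if wrong and abs(gap) > direction_tol_sd * pooled_sd:
            raise DirectionViolationError(
                f"{biomarker or 'biomarker'}: abnormal component median "
                f"({med_e:.3g}) is on the wrong side of the normal median "
                f"({med_ne:.3g}) for direction {direction!r}; review bandwidths"
            )
    return fit


def event_probabilities(
    fit: MixtureFit, x: float | None
) -> tuple[float, float]:
    """Evaluate (P(x|E), P(x|not-E)) at a score residual.

    Missing values return an equal, uninformative pair so a participant's
    likelihood is invariant to where that biomarker sits in the sequence.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return (0.5, 0.5)
    p_e = float(np.interp(x, fit.grid, fit.event_density))
    p_ne = float(np.interp(x, fit.grid, fit.nonevent_density))
    return (p_e, p_ne)
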