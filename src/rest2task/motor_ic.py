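"""Automatic identification of left/right motor components.

Each candidate component is scored by three parameters: (1) distance of its
equivalent dipole (single-sphere fit) to the group-mean motor dipole for the
hemisphere, (2) correlation of its scalp pattern with the group-mean motor
pattern, and (3) mu-band power ratio of its time course (mean PSD over
10-15 Hz divided by mean PSD over 15-20 Hz).  Components whose dipole fit
leaves more than 20% residual variance are rejected first.  The survivors
are ranked per parameter (rank 1 = most motor-like) and the ranks are
combined into a motor index

    f = 3 * I_dist + 1 * I_corr + 2 * I_ratio

per hemisphere; the component with the smallest f wins that hemisphere.
The minimum possible value, f = 6, is attained iff a component is rank-1 on
all three criteria.  Group means are built leave-one-out across subjects so
a subject's own data never enters its template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import welch
from scipy.stats import rankdata

from .decomposition import ComponentTimecourse, Decomposition, sign_normalize
from .forward import gain_matrix

logger = logging.getLogger(__name__)

RV_THRESHOLD = 0.20
MOTOR_WEIGHTS = (3, 1, 2)  # (I_dist, I_corr, I_ratio)
MU_BAND = (10.0, 15.0)     # half-open [10, 15)
NEIGHBOR_BAND = (15.0, 20.0)
#: nominal head radius (mm) used to report head-frame distances on a mm scale
HEAD_RADIUS_MM = 87.5


@dataclass
class DipoleFit:
    """Equivalent-dipole fit of a scalp pattern in the unit-sphere head frame."""

    location: np.ndarray
    moment: np.ndarray
    rv: float  # residual variance: ||pattern - fit||^2 / ||pattern||^2


@dataclass
class Template:
    """Group-mean motor dipoles and scalp patterns for both hemispheres."""

    dipole_left: np.ndarray
    dipole_right: np.ndarray
    pattern_left: np.ndarray
    pattern_right: np.ndarray


@dataclass
class MotorICReport:
    """Per-component scoring table plus the selected left/right components.

    ``table`` columns: rv, power_ratio, then per hemisphere distance,
    correlation, the three 1-based rank indices and the motor index f.
    Rejected components carry NaN in all ranked columns.
    """

    table: pd.DataFrame
    selected_left: int
    selected_right: int
    rv_threshold: float = RV_THRESHOLD
    weights: tuple[int, int, int] = MOTOR_WEIGHTS


# ---------------------------------------------------------------------------
# dipole fitting
# ---------------------------------------------------------------------------

def _grid_points(step: float = 0.1, r_max: float = 0.9) -> np.ndarray:
    ax = np.arange(-r_max, r_max + step / 2, step)
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return pts[np.linalg.norm(pts, axis=1) <= r_max]


@lru_cache(maxsize=4)
def _grid_gains(montage_key: bytes, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    montage = np.frombuffer(montage_key).reshape(shape)
    pts = _grid_points()
    G = np.stack([gain_matrix(p, montage) for p in pts])  # (P, n_ch, 3)
    return pts, G


def _rv_at(loc: np.ndarray, pattern: np.ndarray, montage: np.ndarray) -> tuple[float, np.ndarray]:
    G = gain_matrix(loc, montage)
    m, *_ = np.linalg.lstsq(G, pattern, rcond=None)
    resid = pattern - G @ m
    return float(resid @ resid / (pattern @ pattern)), m


def fit_dipole(pattern: np.ndarray, montage: np.ndarray) -> DipoleFit:
    """Fit a single equivalent dipole to a scalp pattern.

    Coarse search over a 0.1-step interior grid (moment solved in closed
    form by least squares at each node, fully vectorized), then Nelder-Mead
    refinement of the location.  Locations are confined to radius 0.95.
    """
    pattern = np.asarray(pattern, dtype=float)
    energy = float(pattern @ pattern)
    if energy == 0:
        raise ValueError("all-zero pattern cannot be fit")
    montage = np.ascontiguousarray(montage, dtype=float)
    pts, G = _grid_gains(montage.tobytes(), montage.shape)
    # batched least squares via normal equations: m = (G^T G)^-1 G^T p
    GtG = np.einsum("pij,pik->pjk", G, G)
    Gtp = np.einsum("pij,i->pj", G, pattern)
    m_all = np.linalg.solve(GtG, Gtp[..., None])[..., 0]
    explained = np.einsum("pj,pj->p", m_all, Gtp)
    rv_all = 1.0 - explained / energy
    best = int(np.argmin(rv_all))

    def objective(loc: np.ndarray) -> float:
        r = np.linalg.norm(loc)
        if r >= 0.95:
            return 1.0 + r  # keep the search inside the head
        return _rv_at(loc, pattern, montage)[0]

    res = minimize(objective, pts[best], method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
    loc = res.x if objective(res.x) <= rv_all[best] else pts[best]
    rv, m = _rv_at(loc, pattern, montage)
    return DipoleFit(np.asarray(loc, float), m, max(0.0, min(1.0, rv)))


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def rv_gate(rvs: np.ndarray, threshold: float = RV_THRESHOLD) -> np.ndarray:
    """Boolean mask of components surviving the residual-variance gate
    (rv <= threshold).  All-rejected is an error."""
    rvs = np.asarray(rvs, dtype=float)
    keep = rvs <= threshold
    if not keep.any():
        raise ValueError("no candidate motor ICs: all components rejected by RV gate")
    return keep


def power_ratio(
    tc: ComponentTimecourse | np.ndarray,
    fs: float | None = None,
    mu_band: tuple[float, float] = MU_BAND,
    neighbor_band: tuple[float, float] = NEIGHBOR_BAND,
) -> np.ndarray:
    """Mu-to-neighbor PSD ratio per component (Welch, 1-s windows, 50% overlap).

    Bands are half-open on the frequency grid: [10, 15) / [15, 20) Hz by
    default.  A zero denominator yields +inf (logged).
    """
    if isinstance(tc, ComponentTimecourse):
        data, fs = tc.data, tc.fs if fs is None else fs
    else:
        data = np.atleast_2d(np.asarray(tc, dtype=float))
    if fs is None or not np.isfinite(fs):
        raise ValueError("sampling rate required")
    if data.shape[-1] < 2 * fs:
        raise ValueError("need at least 2 s of data")
    nper = int(fs)
    f, pxx = welch(data, fs=fs, nperseg=nper, noverlap=nper // 2, axis=-1)
    num = pxx[..., (f >= mu_band[0]) & (f < mu_band[1])].mean(axis=-1)
    den = pxx[..., (f >= neighbor_band[0]) & (f < neighbor_band[1])].mean(axis=-1)
    with np.errstate(divide="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
    if np.any(den == 0):
        logger.warning("zero neighbor-band power: ratio set to +inf")
    return ratio


def rank_indices(values: np.ndarray, direction: str) -> np.ndarray:
    """1-based ranks, rank 1 = most motor-like.

    ``asc`` ranks smallest first (distances); ``desc`` ranks largest first
    (correlations, power ratios).  Ties go to the earlier component index.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty array")
    if direction == "asc":
        key = values
    elif direction == "desc":
        key = -values
    else:
        raise ValueError(f"direction must be 'asc' or 'desc', got {direction!r}")
    return rankdata(key, method="ordinal").astype(int)


def motor_index(
    i_dist: np.ndarray, i_corr: np.ndarray, i_ratio: np.ndarray,
    weights: tuple[int, int, int] = MOTOR_WEIGHTS,
) -> np.ndarray:
    """Weighted rank combination f = w1*I_dist + w2*I_corr + w3*I_ratio."""
    w1, w2, w3 = weights
    return w1 * np.asarray(i_dist) + w2 * np.asarray(i_corr) + w3 * np.asarray(i_ratio)


# ---------------------------------------------------------------------------
# scoring from raw parameters (the desk-reproducible path)
# ---------------------------------------------------------------------------

def score_components(
    rv: np.ndarray,
    ratio: np.ndarray,
    dist_left: np.ndarray,
    corr_left: np.ndarray,
    dist_right: np.ndarray,
    corr_right: np.ndarray,
    component_ids: np.ndarray | None = None,
    rv_threshold: float = RV_THRESHOLD,
    weights: tuple[int, int, int] = MOTOR_WEIGHTS,
) -> MotorICReport:
    """Score components from their four raw parameters per hemisphere.

    This is the core selection arithmetic, shared by the full pipeline and
    by desk-scale worked examples where the parameters are given directly.
    """
    rv = np.asarray(rv, dtype=float)
    k = len(rv)
    ids = np.arange(1, k + 1) if component_ids is None else np.asarray(component_ids)
    keep = rv_gate(rv, rv_threshold)
    cols: dict[str, np.ndarray] = {"rv": rv, "power_ratio": np.asarray(ratio, float)}
    full = {
        "left": (np.asarray(dist_left, float), np.asarray(corr_left, float)),
        "right": (np.asarray(dist_right, float), np.asarray(corr_right, float)),
    }
    winners: dict[str, int] = {}
    f_win: dict[str, float] = {}
    runner: dict[str, int] = {}
    for side, (dist, corr) in full.items():
        i_dist = rank_indices(dist[keep], "asc")
        i_corr = rank_indices(corr[keep], "desc")
        i_ratio = rank_indices(cols["power_ratio"][keep], "desc")
        f = motor_index(i_dist, i_corr, i_ratio, weights)
        for name, vals in (("dist", dist), ("corr", corr)):
            cols[f"{name}_{side}"] = vals
        for name, vals in (("I_dist", i_dist), ("I_corr", i_corr),
                           ("I_ratio", i_ratio), ("f", f)):
            filled = np.full(k, np.nan)
            filled[keep] = vals
            cols[f"{name}_{side}"] = filled
        # winner = smallest f; equal f is broken by the heaviest-weighted
        # criterion (distance rank), then by component order
        order = np.lexsort((np.arange(keep.sum()), i_dist, f))
        kept_ids = ids[keep]
        winners[side] = int(kept_ids[order[0]])
        f_win[side] = float(f[order[0]])
        runner[side] = int(kept_ids[order[1]]) if len(order) > 1 else winners[side]
    if winners["left"] == winners["right"]:
        # same component minimal on both sides: it keeps the side where its
        # index is smaller, the other side falls back to its runner-up
        give = "right" if f_win["left"] <= f_win["right"] else "left"
        winners[give] = runner[give]
        logger.info("dual-winner conflict resolved: %s side takes runner-up", give)
    table = pd.DataFrame(cols, index=pd.Index(ids, name="component"))
    table["rejected"] = ~keep
    return MotorICReport(table, winners["left"], winners["right"], rv_threshold, weights)


# ---------------------------------------------------------------------------
# full selection from a decomposition
# ---------------------------------------------------------------------------

def select_motor_ics(
    dec: Decomposition,
    tc: ComponentTimecourse,
    template: Template,
    montage: np.ndarray,
    rv_threshold: float = RV_THRESHOLD,
    weights: tuple[int, int, int] = MOTOR_WEIGHTS,
) -> MotorICReport:
    """Score every component of a decomposition against both hemisphere
    templates and select the left/right motor components.

    Dipoles are fit to each scalp pattern; components with rv above the
    threshold are rejected; survivors are ranked on template distance,
    template-pattern correlation, and mu power ratio.  Requires at least two
    survivors.  The report keeps per-component rv and correlations so the
    caller can judge selection quality even in scenes without motor sources.
    """
    k = dec.n_components
    fits = [fit_dipole(dec.patterns[:, j], montage) for j in range(k)]
    rvs = np.array([f.rv for f in fits])
    if (rvs <= rv_threshold).sum() < 2:
        raise ValueError("fewer than 2 components survive the RV gate")
    locs = np.array([f.location for f in fits])
    ratios = power_ratio(tc)
    corr = {}
    dist = {}
    for side, (dip, pat) in (("left", (template.dipole_left, template.pattern_left)),
                             ("right", (template.dipole_right, template.pattern_right))):
        dist[side] = np.linalg.norm(locs - dip[None, :], axis=1)
        pat_n = sign_normalize(pat)
        corr[side] = np.array([
            np.corrcoef(sign_normalize(dec.patterns[:, j]), pat_n)[0, 1] for j in range(k)
        ])
    report = score_components(
        rvs, ratios, dist["left"], corr["left"], dist["right"], corr["right"],
        component_ids=np.arange(k), rv_threshold=rv_threshold, weights=weights,
    )
    report.table["dist_left_mm"] = report.table["dist_left"] * HEAD_RADIUS_MM
    report.table["dist_right_mm"] = report.table["dist_right"] * HEAD_RADIUS_MM
    return report


def loo_templates(
    dipoles: list[dict[str, np.ndarray]], patterns: list[dict[str, np.ndarray]]
) -> list[Template]:
    """Leave-one-out group templates: for each subject, the mean motor dipole
    and (sign-normalized) mean motor pattern over all *other* subjects.

    ``dipoles[i]`` and ``patterns[i]`` map ``'left'``/``'right'`` to subject
    i's motor dipole location and scalp pattern.
    """
    n = len(dipoles)
    if n != len(patterns):
        raise ValueError("dipoles and patterns must cover the same subjects")
    if n < 2:
        raise ValueError("leave-one-out undefined for a single subject")
    out = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        mean_dip = {s: np.mean([dipoles[j][s] for j in others], axis=0) for s in ("left", "right")}
        mean_pat = {
            s: np.mean([sign_normalize(patterns[j][s]) for j in others], axis=0)
            for s in ("left", "right")
        }
        out.append(Template(mean_dip["left"], mean_dip["right"],
                            mean_pat["left"], mean_pat["right"]))
    return out


def canonical_motor_template(montage_labels: list[str], montage: np.ndarray) -> Template:
    """Template from the canonical hand-area dipoles (under C3/C4, radial),
    for use when no cohort is available to build leave-one-out means."""
    from .forward import forward_gain
    from .simulate import motor_dipole_location

    t = {}
    for side in ("left", "right"):
        loc = motor_dipole_location(montage_labels, montage, side)
        g = forward_gain(loc, loc, montage)
        t[side] = (loc, sign_normalize(g / np.linalg.norm(g)))
    return Template(t["left"][0], t["right"][0], t["left"][1], t["right"][1])
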