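"""Potential of mean force, binding energies, escape times and clusters.

The reaction coordinate is the in-plane (2-D) center-of-mass distance r
between two proteins. Umbrella windows restrain r with harmonic biases
``1/2 k_u (r - r_i)^2``; the biased histograms are merged and unbiased by
the standard WHAM self-consistency loop. Because r is a 2-D radial
coordinate, the raw distance distribution carries an entropic ``ln r``
term; by default the PMF is computed as ``W = -k_BT ln P(r) + k_BT ln r +
C`` (the radial Jacobian correction), with a flag to disable it, and the
uncorrected variant is reported alongside.

The binding energy is the depth of the main minimum relative to the
far-field plateau (which defines the zero level). Mean first passage times
out of the bound state follow the standard double integral for overdamped
escape over a tabulated potential,

    tau = (1/D) * int_a^b dy e^{W(y)/kT} int_{r0}^{y} dz e^{-W(z)/kT},

with a the well minimum, b the first zero-level crossing beyond the well,
and a reflecting boundary r0 at the inner edge of the sampled range
(hard-core contact).

Cluster analysis treats proteins as graph vertices with an edge whenever
the minimum bead-bead distance (3-D, so stacked cross-leaflet pairs count)
is below a contact cutoff; clusters are connected components and a cluster
composition's lifetime is its longest contiguous run of frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .state import SimulationState

__all__ = [
    "UmbrellaWindow", "PMFResult", "MFPTResult", "ClusterTimeSeries",
    "umbrella_bias_force", "inplane_com_distance", "wham",
    "binding_energy", "mfpt", "mfpt_quadrature", "detect_clusters",
]


@dataclass
class UmbrellaWindow:
    center: float                  # r_i, in r_c
    k_u: float                     # spring constant, k_BT / r_c^2
    samples: np.ndarray            # production-phase r time series
    equilibration_steps: int = 0
    production_steps: int = 0

    def __post_init__(self):
        if self.k_u < 0:
            raise ValueError("k_u must be non-negative")
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()


@dataclass
class PMFResult:
    r: np.ndarray
    W: np.ndarray                  # k_BT, zero at the far-field plateau
    W_no_jacobian: np.ndarray
    uncertainty: np.ndarray
    counts: np.ndarray
    zero_level_range: tuple
    k_BT: float = 1.0


@dataclass
class MFPTResult:
    tau: float                     # reduced time units
    a: float                       # integration start (well minimum)
    b: float                       # absorbing bound (first zero crossing)
    D: float

    def tau_si(self, tau_unit_ns: float) -> float:
        """Escape time in nanoseconds given the reduced-time unit in ns."""
        return self.tau * tau_unit_ns


@dataclass
class ClusterTimeSeries:
    frames: list                   # per-frame tuple of frozensets (partition)
    lifetimes: dict                # composition -> longest contiguous run (frames)


# ---------------------------------------------------------------- umbrella

def inplane_com_distance(state: SimulationState, beads_a: np.ndarray,
                         beads_b: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-image lateral COM distance and its unit vector a->b."""
    box2 = state.box[:2]
    coms = []
    for idx in (beads_a, beads_b):
        p = state.positions[idx, :2]
        rel = p - p[0]
        rel -= box2 * np.round(rel / box2)
        coms.append(p[0] + rel.mean(axis=0))
    d = coms[1] - coms[0]
    d -= box2 * np.round(d / box2)
    r = float(np.hypot(d[0], d[1]))
    if r > 0:
        return r, d / r
    return r, d


def umbrella_bias_force(
    state: SimulationState,
    beads_a: np.ndarray,
    beads_b: np.ndarray,
    r_center: float,
    k_u: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-bead forces of the harmonic distance restraint.

    The generalized force ``-k_u (r - r_center)`` acts along the in-plane
    COM separation (no z component), distributed uniformly over each
    protein's beads (equal masses), equal and opposite between the two
    proteins so no net momentum is injected.
    """
    r, e = inplane_com_distance(state, beads_a, beads_b)
    if r == 0.0 and r_center > 0:
        # degenerate direction: pick a random in-plane direction
        if rng is None:
            rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2 * np.pi)
        e = np.array([np.cos(phi), np.sin(phi)])
    g = -k_u * (r - r_center)          # along +e on protein b
    forces = np.zeros((state.n_beads, 3))
    fa = -g * e / beads_a.size
    fb = g * e / beads_b.size
    forces[beads_a, 0] += fa[0]
    forces[beads_a, 1] += fa[1]
    forces[beads_b, 0] += fb[0]
    forces[beads_b, 1] += fb[1]
    return forces


# -------------------------------------------------------------------- WHAM

def wham(
    windows: list[UmbrellaWindow],
    k_BT: float = 1.0,
    bin_width: float = 0.05,
    tol: float = 1e-10,
    max_iter: int = 100000,
    jacobian: bool = True,
    plateau_fraction: float = 0.2,
) -> PMFResult:
    """Self-consistent WHAM unbiasing of umbrella windows into a PMF.

    Iterates the window free energies to relative tolerance ``tol`` on
    their maximum change. The unbiased probability is converted to
    ``W(r)`` (with the 2-D radial Jacobian unless disabled) and shifted so
    the mean over the outer ``plateau_fraction`` of the sampled range is
    zero. Per-bin uncertainty is the Poisson estimate ``k_BT /
    sqrt(n)``. Adjacent windows (sorted by center) must have overlapping
    sample support; a gap raises an error naming it.
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 3:
        edges = np.linspace(lo, hi, 3)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nbins = centers.size

    order = np.argsort([w.center for w in windows])
    ws = [windows[i] for i in order]
    hists = np.array([np.histogram(w.samples, bins=edges)[0] for w in ws],
                     dtype=np.float64)
    if len(ws) > 1:
        for k in range(len(ws) - 1):
            hi_k = ws[k].samples.max()
            lo_next = ws[k + 1].samples.min()
            if lo_next > hi_k:
                raise ValueError(
                    f"non-overlapping windows: gap between centers "
                    f"{ws[k].center} and {ws[k + 1].center} "
                    f"(r = {hi_k:.3f} .. {lo_next:.3f})")
    n_i = hists.sum(axis=1)
    n_tot = hists.sum(axis=0)
    bias = np.array([0.5 * w.k_u * (centers - w.center) ** 2 for w in ws])
    boltz = np.exp(-bias / k_BT)                   # (nwin, nbins)

    f = np.zeros(len(ws))
    for it in range(max_iter):
        denom = (n_i[:, None] * np.exp(f[:, None] / k_BT) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_tot / denom, 0.0)
        z = (p[None, :] * boltz).sum(axis=1)
        f_new = -k_BT * np.log(z)
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge within {max_iter} iterations "
            f"(last max |df| = {delta:.3e})")

    with np.errstate(divide="ignore"):
        w_raw = np.where(p > 0, -k_BT * np.log(p), np.nan)
        w_jac = w_raw + k_BT * np.log(centers) if jacobian else w_raw.copy()
    sampled = n_tot > 0
    r_span = centers[sampled]
    plateau_lo = r_span.max() - plateau_fraction * (r_span.max() - r_span.min())
    plateau = sampled & (centers >= plateau_lo)
    zero_j = np.nanmean(w_jac[plateau])
    zero_r = np.nanmean(w_raw[plateau])
    with np.errstate(divide="ignore"):
        unc = np.where(sampled, k_BT / np.sqrt(np.maximum(n_tot, 1)), np.nan)
    return PMFResult(
        r=centers,
        W=w_jac - zero_j,
        W_no_jacobian=w_raw - zero_r,
        uncertainty=unc,
        counts=n_tot,
        zero_level_range=(float(plateau_lo), float(r_span.max())),
        k_BT=k_BT,
    )


def binding_energy(
    pmf: PMFResult,
    width_threshold: float = 1.0,
) -> tuple[float, float, float]:
    """(Delta E, r_min, width) of the PMF's main minimum.

    Delta E = -min W with the zero level at the plateau; width is the
    extent of the contiguous region around the minimum where
    ``W < -width_threshold`` (k_BT), with linear interpolation of the
    crossings. A PMF with no minimum below zero returns (0, nan, 0).
    """
    ok = np.isfinite(pmf.W)
    if not ok.any():
        raise ValueError("PMF has no sampled bins")
    r = pmf.r[ok]
    w = pmf.W[ok]
    imin = int(np.argmin(w))
    if w[imin] >= 0:
        return 0.0, float("nan"), 0.0
    de = float(-w[imin])
    r_min = float(r[imin])
    thr = -width_threshold
    lo_i = imin
    while lo_i > 0 and w[lo_i - 1] < thr:
        lo_i -= 1
    hi_i = imin
    while hi_i < w.size - 1 and w[hi_i + 1] < thr:
        hi_i += 1
    def _cross(i_in, i_out):
        if i_out < 0 or i_out >= w.size:
            return r[i_in]
        w0, w1 = w[i_in], w[i_out]
        if w1 == w0:
            return r[i_in]
        t = (thr - w0) / (w1 - w0)
        return r[i_in] + t * (r[i_out] - r[i_in])
    if w[imin] >= thr:
        return de, r_min, 0.0
    left = _cross(lo_i, lo_i - 1)
    right = _cross(hi_i, hi_i + 1)
    return de, r_min, float(right - left)


# -------------------------------------------------------------------- MFPT

def mfpt_quadrature(
    r: np.ndarray,
    W: np.ndarray,
    D: float,
    a: float,
    b: float,
    r_reflect: float | None = None,
    k_BT: float = 1.0,
    n_grid: int = 4000,
) -> float:
    """Escape-time double integral on a tabulated potential.

    Reflecting boundary at ``r_reflect`` (defaults to the grid start),
    absorbing at ``b``; the outer integral runs from the starting point
    ``a`` to ``b``. Composite trapezoid on a refined uniform grid.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    r = np.asarray(r, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    ok = np.isfinite(W)
    r, W = r[ok], W[ok]
    if r_reflect is None:
        r_reflect = float(r[0])
    if not (r_reflect <= a < b):
        raise ValueError("need r_reflect <= a < b")
    g = np.linspace(r_reflect, b, n_grid)
    wg = np.interp(g, r, W)
    inner = cumulative_trapezoid(np.exp(-wg / k_BT), g, initial=0.0)
    outer_integrand = np.exp(wg / k_BT) * inner
    mask = g >= a
    ga = g[mask]
    fa = outer_integrand[mask]
    if ga[0] > a:   # prepend the exact start point
        ga = np.concatenate([[a], ga])
        fa = np.concatenate([[np.interp(a, g, outer_integrand)], fa])
    tau = np.trapezoid(fa, ga) / D
    return float(tau)


def mfpt(pmf: PMFResult, D: float) -> MFPTResult:
    """Mean first passage time out of the PMF's main well.

    ``a`` is the well minimum, ``b`` the closest distance beyond it where
    the PMF reaches the zero level (linear interpolation); raises if the
    PMF never crosses zero inside the sampled grid.
    """
    ok = np.isfinite(pmf.W)
    r = pmf.r[ok]
    w = pmf.W[ok]
    imin = int(np.argmin(w))
    if w[imin] >= 0:
        raise ValueError("PMF has no well below the zero level")
    a = float(r[imin])
    b = None
    for i in range(imin + 1, w.size):
        if w[i] >= 0.0:
            w0, w1 = w[i - 1], w[i]
            t = (0.0 - w0) / (w1 - w0) if w1 != w0 else 0.0
            b = float(r[i - 1] + t * (r[i] - r[i - 1]))
            break
    if b is None:
        raise ValueError("PMF never returns to the zero level beyond the well")
    tau = mfpt_quadrature(r, w, D, a, b, r_reflect=float(r[0]),
                          k_BT=pmf.k_BT)
    return MFPTResult(tau=tau, a=a, b=b, D=D)


def bootstrap_well_depth(
    windows: list[UmbrellaWindow],
    n_boot: int = 200,
    block: int = 50,
    seed: int = 0,
    **wham_kwargs,
) -> np.ndarray:
    """Block-bootstrap distribution of the binding energy.

    Each window's time series is resampled in contiguous blocks of
    ``block`` samples (preserving short-range correlation), WHAM is rerun
    and the well depth extracted; returns the ``n_boot`` depths, whose
    spread estimates the statistical uncertainty of Delta E.
    """
    rng = np.random.default_rng(seed)
    depths = np.empty(n_boot)
    for b in range(n_boot):
        resampled = []
        for w in windows:
            s = w.samples
            nblk = max(1, s.size // block)
            starts = rng.integers(0, max(1, s.size - block + 1), size=nblk)
            chunks = [s[st:st + block] for st in starts]
            resampled.append(UmbrellaWindow(center=w.center, k_u=w.k_u,
                                            samples=np.concatenate(chunks)))
        res = wham(resampled, **wham_kwargs)
        depths[b], _, _ = binding_energy(res)
    return depths


# ---------------------------------------------------------------- clusters

def _min_interprotein_distance(state: SimulationState, ia: np.ndarray,
                               ib: np.ndarray) -> float:
    d = state.positions[ia, None, :] - state.positions[None, ib, :]
    d -= state.box * np.round(d / state.box)
    return float(np.sqrt(np.einsum("ijk,ijk->ij", d, d).min()))


def detect_clusters(
    frames,
    protein_beads: dict[int, np.ndarray],
    cutoff: float = 1.0,
) -> ClusterTimeSeries:
    """Connected-component clusters of proteins over a trajectory.

    ``protein_beads`` maps protein labels to bead-index arrays. Two
    proteins are in contact when their minimum bead-bead distance (full
    3-D minimum image, so stacked cross-leaflet pairs qualify) is below
    ``cutoff``. Each frame's partition is the set of connected
    components; a composition's lifetime is its longest contiguous run.
    """
    labels = sorted(protein_beads)
    if len(labels) < 2:
        raise ValueError("cluster analysis needs at least two proteins")
    partitions = []
    for state in frames:
        parent = {l: l for l in labels}
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                if _min_interprotein_distance(
                        state, protein_beads[la], protein_beads[lb]) < cutoff:
                    parent[find(la)] = find(lb)
        comps = {}
        for l in labels:
            comps.setdefault(find(l), set()).add(l)
        partitions.append(tuple(sorted(
            (frozenset(c) for c in comps.values()),
            key=lambda c: sorted(c))))
    lifetimes: dict[frozenset, int] = {}
    current: dict[frozenset, int] = {}
    for part in partitions:
        present = set(part)
        for comp in present:
            current[comp] = current.get(comp, 0) + 1
            lifetimes[comp] = max(lifetimes.get(comp, 0), current[comp])
        for comp in list(current):
            if comp not in present:
                del current[comp]
    return ClusterTimeSeries(frames=partitions, lifetimes=lifetimes)
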