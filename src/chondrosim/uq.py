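"""Polynomial-chaos uncertainty quantification and Sobol sensitivities.

Uniform uncertain parameters are expanded in a total-degree orthonormal
(shifted) Legendre basis; expansion coefficients come from point
collocation: the model is evaluated at 2M + 2 random parameter draws
(M = C(d+p, p) basis terms) and fitted by least squares.  Means, variances
and first-order Sobol indices follow algebraically from the orthonormal
coefficients; percentiles are empirical over 10⁴ surrogate samples.

Two canonical studies are provided: geometric uncertainty of a movable
cell next to a fixed copy (case 1: x, y, z position, volume, orientation
angle) and uncertainty of the membrane thickness and dielectric parameters
on a fixed geometry (case 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .dielectric import extract_dielectric
from .geometry import TissueGeometry, ellipsoids_intersect, voxelize_geometry
from .solver import MaterialProps, frequency_sweep
from .types import EllipsoidCell, EllipsoidSet


@dataclass
class UncertainParameter:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")


class NodeRejected(RuntimeError):
    """Raised by a model to reject an invalid parameter draw (redrawn)."""


def pce_node_count(d: int, p: int) -> int:
    """Collocation budget 2·C(d+p, p) + 2 (e.g. d=5, p=4 → 254)."""
    if d < 1 or p < 0:
        raise ValueError("need d >= 1 and p >= 0")
    return 2 * comb(d + p, p) + 2


def _multi_indices(d: int, p: int) -> np.ndarray:
    """All d-dimensional exponent tuples of total degree <= p, graded order."""
    out = []
    for deg in range(p + 1):
        for idx in itertools.combinations_with_replacement(range(d), deg):
            counts = [0] * d
            for i in idx:
                counts[i] += 1
            out.append(tuple(counts))
    return np.array(sorted(set(out), key=lambda t: (sum(t), t)), dtype=int)


def _legendre_table(t: np.ndarray, p: int) -> np.ndarray:
    """Orthonormal Legendre values φ_k(t) = √(2k+1)·P_k(t), t ∈ [-1, 1];
    returns shape (len(t), p+1)."""
    vals = np.empty((t.size, p + 1))
    vals[:, 0] = 1.0
    if p >= 1:
        vals[:, 1] = t
    for k in range(1, p):
        vals[:, k + 1] = ((2 * k + 1) * t * vals[:, k] - k * vals[:, k - 1]) / (k + 1)
    return vals * np.sqrt(2 * np.arange(p + 1) + 1)


@dataclass
class PCESurrogate:
    params: list[UncertainParameter]
    order: int
    multi_indices: np.ndarray  # (M, d)
    coefficients: np.ndarray  # (M, n_outputs)
    output_shape: tuple
    nodes: np.ndarray  # (n_nodes, d)
    evaluations: np.ndarray  # (n_nodes, n_outputs)

    @property
    def dimension(self) -> int:
        return len(self.params)

    @property
    def basis_size(self) -> int:
        return len(self.multi_indices)

    def _design(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        tables = []
        for j, prm in enumerate(self.params):
            t = 2.0 * (x[:, j] - prm.low) / (prm.high - prm.low) - 1.0
            tables.append(_legendre_table(t, self.order))
        phi = np.ones((x.shape[0], self.basis_size))
        for m, idx in enumerate(self.multi_indices):
            for j, k in enumerate(idx):
                if k:
                    phi[:, m] *= tables[j][:, k]
        return phi

    def __call__(self, x: np.ndarray) -> np.ndarray:
        phi = self._design(x)
        out = phi @ self.coefficients
        return out.reshape((len(phi),) + self.output_shape)

    @property
    def mean(self) -> np.ndarray:
        return self.coefficients[0].reshape(self.output_shape)

    @property
    def variance(self) -> np.ndarray:
        return np.sum(self.coefficients[1:] ** 2, axis=0).reshape(self.output_shape)


def build_surrogate(
    model,
    params: list[UncertainParameter],
    order: int = 4,
    seed: int = 0,
    max_redraws: int = 50,
) -> PCESurrogate:
    """Point-collocation PCE of ``model(x) -> array`` over uniform inputs.

    Nodes are pseudo-random draws from the joint uniform distribution
    (seeded); a model may raise :class:`NodeRejected` for invalid draws,
    which are replaced to keep the design size at 2M + 2.
    """
    d = len(params)
    mi = _multi_indices(d, order)
    m_basis = len(mi)
    n_nodes = pce_node_count(d, order)
    rng = np.random.default_rng(seed)
    lows = np.array([p.low for p in params])
    highs = np.array([p.high for p in params])

    nodes, evals = [], []
    attempts = 0
    while len(nodes) < n_nodes:
        if attempts > max_redraws * n_nodes:
            raise RuntimeError("too many rejected collocation nodes")
        attempts += 1
        x = rng.uniform(lows, highs)
        try:
            y = np.asarray(model(x), dtype=float)
        except NodeRejected:
            continue
        nodes.append(x)
        evals.append(y)
    nodes = np.array(nodes)
    out_shape = evals[0].shape
    y_mat = np.array([e.ravel() for e in evals])

    surrogate = PCESurrogate(params, order, mi, np.zeros((m_basis, y_mat.shape[1])),
                             out_shape, nodes, y_mat)
    phi = surrogate._design(nodes)
    coeffs, _, rank, _ = np.linalg.lstsq(phi, y_mat, rcond=None)
    if rank < m_basis:
        raise RuntimeError(
            f"rank-deficient collocation matrix (rank {rank} < {m_basis}); "
            "increase the node count"
        )
    surrogate.coefficients = coeffs
    return surrogate


def sobol_first_order(s: PCESurrogate) -> np.ndarray:
    """First-order Sobol index per parameter, shape (d, *output_shape).

    S_i sums squared coefficients of basis terms depending on parameter i
    alone, normalized by the total variance; all-zero variance yields 0.
    """
    var = np.sum(s.coefficients[1:] ** 2, axis=0)
    out = np.zeros((s.dimension,) + (s.coefficients.shape[1],))
    for i in range(s.dimension):
        only_i = (s.multi_indices[:, i] > 0) & (
            np.sum(s.multi_indices > 0, axis=1) == 1
        )
        out[i] = np.sum(s.coefficients[only_i] ** 2, axis=0)
    tiny = 1e-24 * (1.0 + s.coefficients[0] ** 2)  # zero up to round-off
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(var > tiny, out / var, 0.0)
    return out.reshape((s.dimension,) + s.output_shape)


def prediction_interval(
    s: PCESurrogate, n_samples: int = 10_000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 5th/95th percentiles from surrogate Monte-Carlo samples."""
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    rng = np.random.default_rng(seed)
    lows = np.array([p.low for p in s.params])
    highs = np.array([p.high for p in s.params])
    x = rng.uniform(lows, highs, size=(n_samples, s.dimension))
    y = s(x)
    return np.percentile(y, 5, axis=0), np.percentile(y, 95, axis=0)


@dataclass
class UQResult:
    frequencies: np.ndarray
    quantities: tuple[str, ...]  # e.g. ("sigma_eff", "eps_r_eff")
    parameter_names: tuple[str, ...]
    mean: np.ndarray  # (n_qty, n_freq)
    variance: np.ndarray
    p5: np.ndarray
    p95: np.ndarray
    sobol: np.ndarray  # (n_params, n_qty, n_freq)
    surrogate: PCESurrogate | None = field(default=None, repr=False)


def _aggregate(surrogate, frequencies, quantities, params, n_samples, seed) -> UQResult:
    p5, p95 = prediction_interval(surrogate, n_samples, seed)
    return UQResult(
        frequencies=np.asarray(frequencies, dtype=float),
        quantities=tuple(quantities),
        parameter_names=tuple(p.name for p in params),
        mean=surrogate.mean,
        variance=surrogate.variance,
        p5=p5,
        p95=p95,
        sobol=sobol_first_order(surrogate),
        surrogate=surrogate,
    )


def _run_parametric(
    model_full,
    specs: list[tuple[str, float, float]],
    frequencies,
    order: int,
    seed: int,
    n_prediction_samples: int,
) -> UQResult:
    """Shared driver: collapsed (low == high) parameters are held constant
    and excluded from the expansion; with no active parameter the model is
    evaluated once at the nominal point (zero variance by construction)."""
    active = [(i, UncertainParameter(n, lo, hi)) for i, (n, lo, hi) in enumerate(specs)
              if lo < hi]
    nominal = np.array([(lo + hi) / 2.0 for _, lo, hi in specs])
    freqs = np.asarray(frequencies, dtype=float)
    if not active:
        y = np.asarray(model_full(nominal), dtype=float)
        zeros = np.zeros_like(y)
        return UQResult(freqs, ("sigma_eff", "eps_r_eff"),
                        tuple(n for n, _, _ in specs), y, zeros, y.copy(), y.copy(),
                        np.zeros((len(specs),) + y.shape))

    idx = [i for i, _ in active]
    params = [p for _, p in active]

    def model(x: np.ndarray) -> np.ndarray:
        full = nominal.copy()
        full[idx] = x
        return model_full(full)

    surrogate = build_surrogate(model, params, order=order, seed=seed)
    res = _aggregate(surrogate, freqs, ("sigma_eff", "eps_r_eff"),
                     params, n_prediction_samples, seed)
    # report every requested parameter, inactive ones with zero index
    sobol = np.zeros((len(specs),) + surrogate.output_shape)
    sobol[idx] = res.sobol
    res.sobol = sobol
    res.parameter_names = tuple(n for n, _, _ in specs)
    return res


def _rotation_about(axis: int, angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))
    i, j = [a for a in range(3) if a != axis]
    rot = np.eye(3)
    rot[i, i], rot[i, j], rot[j, i], rot[j, j] = c, -s, s, c
    return rot


#: Inter-cell surface distance span probed by the geometric UQ (µm).
CASE1_DISTANCE_SPAN = (4.5, 22.5)


def default_case1_setup(
    volume: float = 2157.0,
    box_size: float = 54.0,
    axis_ratios: tuple[float, float, float] = (1.5, 1.2, 1.0),
):
    """Movable ellipsoid at the box center, fixed copy towards the
    top-right corner, with position ranges constructed so the nominal
    surface-to-surface distance spans exactly CASE1_DISTANCE_SPAN."""
    q = np.asarray(axis_ratios, dtype=float)
    c = (3.0 * volume / (4.0 * np.pi * np.prod(q))) ** (1.0 / 3.0)
    semi = q * c
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    d_lo = CASE1_DISTANCE_SPAN[0] + 2 * r_eq
    d_hi = CASE1_DISTANCE_SPAN[1] + 2 * r_eq
    offset = (d_lo + d_hi) / 2.0 / np.sqrt(3.0)
    half_width = (d_hi - d_lo) / 2.0 / np.sqrt(3.0)
    box = np.full(3, box_size)
    center = box / 2.0
    base = EllipsoidCell(center, semi, np.eye(3), label=1)
    fixed = EllipsoidCell(center + offset, semi, np.eye(3), label=2)
    return base, fixed, box, half_width


def run_case1(
    base_cell: EllipsoidCell | None = None,
    fixed_cell: EllipsoidCell | None = None,
    box: np.ndarray | None = None,
    props: MaterialProps | None = None,
    position_half_width: float | None = None,
    volume_fraction_range: float = 0.25,
    angle_range: tuple[float, float] = (0.0, 90.0),
    rotation_axis: int = 1,
    grid_shape: int = 32,
    frequencies: np.ndarray | None = None,
    order: int = 4,
    seed: int = 0,
    n_prediction_samples: int = 10_000,
    solver_tol: float = 1e-8,
) -> UQResult:
    """Geometric uncertainty: x, y, z position, volume and angle of a
    movable cell next to a fixed copy; outputs σ_eff and ε_r_eff spectra.

    Draws where the movable cell would intersect the fixed copy are
    rejected and redrawn.
    """
    props = props or MaterialProps()
    if base_cell is None:
        base_cell, fixed_default, box_default, w_default = default_case1_setup()
        fixed_cell = fixed_cell if fixed_cell is not None else fixed_default
        box = box if box is not None else box_default
        if position_half_width is None:
            position_half_width = w_default
    if fixed_cell is None or box is None or position_half_width is None:
        raise ValueError("base_cell, fixed_cell, box and position_half_width go together")
    box = np.asarray(box, dtype=float)
    if frequencies is None:
        frequencies = np.logspace(4, 9, 6)
    voxel = float(box[0]) / grid_shape
    nominal_volume = base_cell.volume
    c0 = base_cell.center
    w = position_half_width
    specs = [
        ("z", c0[0] - w, c0[0] + w),
        ("y", c0[1] - w, c0[1] + w),
        ("x", c0[2] - w, c0[2] + w),
        ("volume", (1 - volume_fraction_range) * nominal_volume,
         (1 + volume_fraction_range) * nominal_volume),
        ("angle", angle_range[0], angle_range[1]),
    ]
    sep = box[0] * 1e-6
    area = box[1] * box[2] * 1e-12

    def model(x: np.ndarray) -> np.ndarray:
        center = x[:3]
        scale = (x[3] / nominal_volume) ** (1.0 / 3.0)
        rot = _rotation_about(rotation_axis, x[4]) @ base_cell.rotation
        movable = EllipsoidCell(center, base_cell.semi_axes * scale, rot, label=1)
        if ellipsoids_intersect(movable, fixed_cell):
            raise NodeRejected
        cells = EllipsoidSet([movable, fixed_cell], box)
        geom = voxelize_geometry(cells, box, voxel, electrode_axis=0)
        spec = frequency_sweep(geom, props, frequencies=frequencies, tol=solver_tol)
        diel = extract_dielectric(spec, sep, area)
        return np.stack([diel.sigma_eff, diel.eps_r_eff])

    return _run_parametric(model, specs, frequencies, order, seed, n_prediction_samples)


CASE2_ALL = ("d_m", "sigma_m", "sigma_cyt", "sigma_buf", "eps_rm", "eps_rcyt", "eps_rbuf")
CASE2_CELLULAR = ("d_m", "sigma_m", "sigma_cyt", "eps_rm", "eps_rcyt")


def run_case2(
    geom: TissueGeometry,
    nominal: MaterialProps | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    fix_extracellular: bool = False,
    relative_range: float = 0.25,
    frequencies: np.ndarray | None = None,
    order: int = 4,
    seed: int = 0,
    n_prediction_samples: int = 10_000,
    solver_tol: float = 1e-8,
) -> UQResult:
    """Dielectric-parameter uncertainty on a fixed geometry.

    Seven uniform parameters (membrane thickness and all conductivities /
    permittivities), or the five cellular ones when the extracellular
    medium is fixed; defaults are ±``relative_range`` around nominal.
    """
    nominal = nominal or MaterialProps()
    if frequencies is None:
        frequencies = np.logspace(4, 9, 6)
    names = CASE2_CELLULAR if fix_extracellular else CASE2_ALL
    specs = []
    for name in names:
        if ranges and name in ranges:
            lo, hi = ranges[name]
        else:
            val = getattr(nominal, name)
            lo, hi = (1 - relative_range) * val, (1 + relative_range) * val
        specs.append((name, lo, hi))
    sep = geom.box[0] * 1e-6
    area = geom.box[1] * geom.box[2] * 1e-12

    def model(x: np.ndarray) -> np.ndarray:
        kwargs = dict(zip(names, map(float, x)))
        props = MaterialProps(
            **{
                f: kwargs.get(f, getattr(nominal, f))
                for f in ("sigma_m", "sigma_cyt", "sigma_buf", "eps_rm",
                          "eps_rcyt", "eps_rbuf", "d_m")
            }
        )
        spec = frequency_sweep(geom, props, frequencies=frequencies, tol=solver_tol)
        diel = extract_dielectric(spec, sep, area)
        return np.stack([diel.sigma_eff, diel.eps_r_eff])

    return _run_parametric(model, specs, frequencies, order, seed, n_prediction_samples)
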