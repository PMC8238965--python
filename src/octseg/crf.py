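"""Fully-connected CRF refinement of coarse probability maps.

The coarse per-pixel probabilities from the classifier define unary
potentials ψ_u(X_i) = −log P(X_i); every *pair* of pixels is coupled by a
pairwise potential

    ψ_p(X_i, X_j) = μ(X_i, X_j) · Σ_m ω^(m) k^(m)(i, j)

with Gaussian kernels over position p and appearance f,

    k(i, j) = exp(−|p_i − p_j|² / 2θα² − |f_i − f_j|² / 2θβ²),

so θα sets the spatial reach ("nearness") and θβ the tolerated gray-level
difference ("similarity"). μ is the Potts compatibility by default
(penalty 1 for disagreeing labels, 0 otherwise). The refined labeling
approximately minimizes the Gibbs energy

    E(X | I) = Σ_i ψ_u(X_i) + Σ_{i<j} ψ_p(X_i, X_j)

by mean-field iteration: each pixel keeps an independent marginal Q_i,
updated as Q_i(l) ∝ exp(−ψ_u(l) − Σ_{l'} μ(l,l') Σ_m ω^(m) Σ_{j≠i}
k^(m)(i,j) Q_j(l')).

Two inference backends are provided: ``dense`` materializes the full
N×N kernel matrices (exact message passing; small images), ``filtered``
approximates the bilateral message with Gaussian filtering on a
position×intensity grid (large images). A brute-force enumerator gives
the exact MAP for tiny problems and serves as an oracle. Feature values
f are presented on the 0–255 gray scale by contract, matching the scale
on which the default θβ = 8 is meaningful; the defaults θα = 16, θβ = 8
sit at the F1 optimum of the sensitivity sweep implemented in
:func:`sweep_theta`.

By default the kernels are symmetrically degree-normalized,
k̂(i,j) = k(i,j)/sqrt(d_i d_j) with d_i = Σ_j k(i,j): raw kernel sums
grow with image area and would let the pairwise messages swamp the unary
evidence on anything beyond toy sizes, whereas normalized messages stay
O(1). Normalization is applied consistently in the energy, the mean-field
messages and the brute-force oracle, so the three views optimize the same
objective; ``kernel_normalization="none"`` recovers the literal raw-sum
model. The default coupling weight ω = 3 is calibrated so that, on the
normalized scale, a locally isolated error of unary confidence ≤ 0.9
inside a homogeneous region is overruled by its neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product as _iter_product

import numpy as np
from scipy.ndimage import gaussian_filter

_DENSE_AUTO_LIMIT = 1500  # pixels; above this "auto" switches to filtered


@dataclass(frozen=True)
class CRFParams:
    theta_alpha: float = 16.0       # spatial scale, pixels
    theta_beta: float = 8.0         # appearance scale, gray levels (0-255)
    kernel_weights: tuple[float, ...] = (3.0,)
    theta_gamma: float = 3.0        # spatial scale of the optional 2nd kernel
    compatibility: str = "potts"
    n_iterations: int = 10
    inference_mode: str = "auto"    # dense | filtered | auto
    kernel_normalization: str = "symmetric"  # symmetric | none

    def __post_init__(self):
        if self.theta_alpha <= 0 or self.theta_beta <= 0 or self.theta_gamma <= 0:
            raise ValueError("theta scales must be > 0")
        if any(w < 0 for w in self.kernel_weights):
            raise ValueError("kernel weights must be >= 0")
        if len(self.kernel_weights) not in (1, 2):
            raise ValueError(
                "kernel_weights has one entry (bilateral kernel) or two "
                "(bilateral + spatial smoothness)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.inference_mode not in ("dense", "filtered", "auto"):
            raise ValueError("inference_mode must be dense, filtered or auto")
        if self.kernel_normalization not in ("symmetric", "none"):
            raise ValueError("kernel_normalization must be 'symmetric' or 'none'")

    @property
    def n_kernels(self) -> int:
        return len(self.kernel_weights)

    def mu_matrix(self, n_labels: int) -> np.ndarray:
        if self.compatibility != "potts":
            raise ValueError(f"unknown compatibility '{self.compatibility}'")
        return 1.0 - np.eye(n_labels)


@dataclass
class CRFProblem:
    """Unary potentials plus the image supplying features and coordinates."""

    unary: np.ndarray      # (H, W, L) potentials ψ_u
    features: np.ndarray   # (H, W) gray values on the 0-255 scale
    n_labels: int = 2

    def __post_init__(self):
        self.unary = np.asarray(self.unary, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.unary.ndim != 3 or self.unary.shape[:2] != self.features.shape:
            raise ValueError("unary must be (H, W, L) matching the feature image")
        if not np.all(np.isfinite(self.unary)):
            raise ValueError("unary potentials must be finite")
        self.n_labels = self.unary.shape[-1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.features.shape

    @property
    def n_pixels(self) -> int:
        return self.unary.shape[0] * self.unary.shape[1]


def unary_from_proba(proba: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """ψ_u(X_i = l) = −log max(P_l(i), eps)."""
    return -np.log(np.clip(np.asarray(proba, dtype=np.float64), eps, None))


def make_problem(proba: np.ndarray, image01: np.ndarray,
                 eps: float = 1e-10) -> CRFProblem:
    """Build a refinement problem from a probability map and a [0,1] image."""
    return CRFProblem(unary=unary_from_proba(proba, eps),
                      features=np.asarray(image01, dtype=np.float64) * 255.0)


def gaussian_kernel(p_i, p_j, f_i, f_j, theta_alpha: float,
                    theta_beta: float) -> float:
    """Bilateral similarity in (0, 1] between two pixels."""
    if theta_alpha <= 0 or theta_beta <= 0:
        raise ValueError("theta scales must be > 0")
    dp = np.asarray(p_i, dtype=np.float64) - np.asarray(p_j, dtype=np.float64)
    df = np.asarray(f_i, dtype=np.float64) - np.asarray(f_j, dtype=np.float64)
    return float(np.exp(-(dp @ dp) / (2 * theta_alpha**2)
                        - np.dot(df, df) / (2 * theta_beta**2)))


def pairwise_potential(label_i: int, label_j: int, k_values,
                       params: CRFParams) -> float:
    """ψ_p for one pixel pair given its per-kernel similarities."""
    k_values = np.atleast_1d(np.asarray(k_values, dtype=np.float64))
    if len(k_values) != params.n_kernels:
        raise ValueError(
            f"{len(k_values)} kernel values for {params.n_kernels} weights")
    mu = params.mu_matrix(max(label_i, label_j) + 1)[label_i, label_j]
    return float(mu * np.dot(params.kernel_weights, k_values))


def _normalize_kernel(k: np.ndarray, params: CRFParams) -> np.ndarray:
    """Optional symmetric degree normalization k̂ = k / sqrt(d_i d_j).

    Degrees include the (unit) self-similarity, matching the grid-filtered
    backend; the diagonal itself stays zero (no self-coupling in messages
    or energies). Normalization keeps mean-field messages O(1) regardless
    of image size, the convention of standard dense-CRF inference.
    """
    if params.kernel_normalization == "none":
        return k
    d = k.sum(axis=1) + 1.0
    inv = 1.0 / np.sqrt(d)
    return k * inv[:, None] * inv[None, :]


def _kernel_matrices(problem: CRFProblem, params: CRFParams) -> list[np.ndarray]:
    """Dense (N, N) similarity matrices, zero diagonal (no self-coupling)."""
    h, w = problem.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pos = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float64)
    feat = problem.features.ravel()
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    ks = []
    bilateral = np.exp(-d2 / (2 * params.theta_alpha**2)
                       - (feat[:, None] - feat[None, :]) ** 2
                       / (2 * params.theta_beta**2))
    np.fill_diagonal(bilateral, 0.0)
    ks.append(_normalize_kernel(bilateral, params))
    if params.n_kernels == 2:
        spatial = np.exp(-d2 / (2 * params.theta_gamma**2))
        np.fill_diagonal(spatial, 0.0)
        ks.append(_normalize_kernel(spatial, params))
    return ks


def total_energy(labeling: np.ndarray, problem: CRFProblem,
                 params: CRFParams) -> float:
    """Gibbs energy E = Σ_i ψ_u + Σ_{i<j} ψ_p (each unordered pair once)."""
    labeling = np.asarray(labeling)
    if labeling.shape != problem.shape:
        raise ValueError("labeling shape does not match problem")
    if labeling.min() < 0 or labeling.max() >= problem.n_labels:
        raise ValueError("labeling contains labels outside the label set")
    lab = labeling.ravel()
    idx = np.arange(problem.n_pixels)
    e_unary = float(problem.unary.reshape(-1, problem.n_labels)[idx, lab].sum())
    mu = params.mu_matrix(problem.n_labels)
    pair_mu = mu[lab[:, None], lab[None, :]]
    e_pair = 0.0
    for w_m, k_m in zip(params.kernel_weights, _kernel_matrices(problem, params)):
        e_pair += w_m * 0.5 * float((pair_mu * k_m).sum())  # diag already 0
    return e_unary + e_pair


def unary_argmin(problem: CRFProblem) -> np.ndarray:
    """Labeling from unary potentials alone (the classifier's argmax)."""
    return np.argmin(problem.unary, axis=-1)


def _mean_field_dense(problem: CRFProblem, params: CRFParams) -> np.ndarray:
    n, L = problem.n_pixels, problem.n_labels
    unary = problem.unary.reshape(n, L)
    ks = _kernel_matrices(problem, params)
    mu = params.mu_matrix(L)
    q = _normalize(np.exp(-unary))
    for _ in range(params.n_iterations):
        msg = np.zeros_like(q)
        for w_m, k_m in zip(params.kernel_weights, ks):
            msg += w_m * (k_m @ q)
        q = _normalize(np.exp(-unary - msg @ mu.T))
    return q.reshape(problem.unary.shape)


def _normalize(q: np.ndarray) -> np.ndarray:
    return q / q.sum(axis=-1, keepdims=True)


def _grid_message(q: np.ndarray, coords: list[np.ndarray],
                  sizes: tuple[int, ...]) -> np.ndarray:
    """Approximate Σ_j exp(-||g_i - g_j||²/2) q_j by splat → blur → slice
    on an integer grid whose axes are already scaled to unit sigma."""
    L = q.shape[-1]
    flat = np.ravel_multi_index(coords, sizes)
    grid = np.zeros((int(np.prod(sizes)), L))
    np.add.at(grid, flat, q.reshape(-1, L))
    grid = grid.reshape(*sizes, L)
    # scipy normalizes its kernel; rescale so the blur realizes the raw
    # sum Σ exp(-d²/2) over grid cells
    radius = 4
    taps = np.exp(-0.5 * np.arange(-radius, radius + 1) ** 2)
    scale = taps.sum() ** len(sizes)
    blurred = gaussian_filter(grid, sigma=(1.0,) * len(sizes) + (0.0,),
                              mode="constant", truncate=float(radius))
    return blurred.reshape(-1, L)[flat] * scale


def _mean_field_filtered(problem: CRFProblem, params: CRFParams) -> np.ndarray:
    h, w = problem.shape
    L = problem.n_labels
    unary = problem.unary.reshape(-1, L)
    yy, xx = np.mgrid[0:h, 0:w]

    def grid_coords(scales_feats):
        coords, sizes = [], []
        for arr, sigma in scales_feats:
            c = np.rint(arr.ravel() / sigma).astype(np.intp)
            c -= c.min()
            coords.append(c)
            sizes.append(int(c.max()) + 1)
        return coords, tuple(sizes)

    kernels = [grid_coords([(yy, params.theta_alpha), (xx, params.theta_alpha),
                            (problem.features, params.theta_beta)])]
    if params.n_kernels == 2:
        kernels.append(grid_coords([(yy, params.theta_gamma),
                                    (xx, params.theta_gamma)]))

    # per-kernel degrees d_i = Σ_j k(i,j) (self included), for normalization
    ones = np.ones((h * w, 1))
    inv_sqrt_d = []
    for coords, sizes in kernels:
        d = np.maximum(_grid_message(ones, coords, sizes)[:, 0], 1.0)
        inv_sqrt_d.append(1.0 / np.sqrt(d))

    mu = params.mu_matrix(L)
    q = _normalize(np.exp(-unary))
    for _ in range(params.n_iterations):
        msg = np.zeros_like(q)
        for w_m, (coords, sizes), isd in zip(params.kernel_weights, kernels,
                                             inv_sqrt_d):
            if params.kernel_normalization == "symmetric":
                filt = isd[:, None] * _grid_message(q * isd[:, None],
                                                    coords, sizes)
                msg += w_m * (filt - q * (isd**2)[:, None])  # drop self-term
            else:
                msg += w_m * (_grid_message(q, coords, sizes) - q)
        q = _normalize(np.exp(-unary - msg @ mu.T))
    return q.reshape(problem.unary.shape)


def mean_field_infer(problem: CRFProblem,
                     params: CRFParams = CRFParams()) -> tuple[np.ndarray, np.ndarray]:
    """Mean-field refinement; returns (marginals (H,W,L), labeling (H,W)).

    In dense mode the returned labeling is additionally guaranteed never
    to have higher Gibbs energy than the unary-argmax labeling: if the
    fixed-iteration mean field ends in a worse state, the unary argmax is
    returned instead.
    """
    mode = params.inference_mode
    if mode == "auto":
        mode = "dense" if problem.n_pixels <= _DENSE_AUTO_LIMIT else "filtered"
    if mode == "dense":
        marginals = _mean_field_dense(problem, params)
    else:
        marginals = _mean_field_filtered(problem, params)
    labeling = np.argmax(marginals, axis=-1)
    if mode == "dense":
        baseline = unary_argmin(problem)
        if (total_energy(labeling, problem, params)
                > total_energy(baseline, problem, params)):
            labeling = baseline
    return marginals, labeling


def refine(proba: np.ndarray, image01: np.ndarray,
           params: CRFParams = CRFParams()) -> tuple[np.ndarray, np.ndarray]:
    """Refine a coarse probability map against its (denoised) image."""
    return mean_field_infer(make_problem(proba, image01), params)


def brute_force_map(problem: CRFProblem,
                    params: CRFParams = CRFParams()) -> np.ndarray:
    """Exact MAP by exhaustive enumeration (|L|^N ≤ 2^20).

    Ties are broken toward the lexicographically smallest labeling, which
    is the first one enumerated.
    """
    n, L = problem.n_pixels, problem.n_labels
    if L**n > 2**20:
        raise ValueError(
            f"{L}^{n} labelings exceed the enumeration limit; use "
            "mean_field_infer for problems this size")
    unary = problem.unary.reshape(n, L)
    ks = _kernel_matrices(problem, params)
    s = sum(w * k for w, k in zip(params.kernel_weights, ks))
    labelings = np.array(list(_iter_product(range(L), repeat=n)), dtype=np.intp)
    best_energy, best_idx = np.inf, 0
    chunk = 8192  # keeps the (chunk, n, n) disagreement tensor small
    for start in range(0, len(labelings), chunk):
        lab = labelings[start : start + chunk]
        e_unary = unary[np.arange(n), lab].sum(axis=1)
        diff = lab[:, :, None] != lab[:, None, :]
        energy = e_unary + 0.5 * (diff * s[None]).sum(axis=(1, 2))
        i = int(np.argmin(energy))  # first minimum == lexicographic tie-break
        if energy[i] < best_energy:
            best_energy, best_idx = float(energy[i]), start + i
    return labelings[best_idx].reshape(problem.shape)


@dataclass
class SweepResult:
    surface: list[dict] = field(default_factory=list)
    best: dict | None = None

    def curve(self, theta_alpha: float) -> list[dict]:
        """The fixed-θα slice: mean F1 as a function of θβ."""
        return [e for e in self.surface if e["theta_alpha"] == theta_alpha]


def sweep_theta(instances: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                theta_alphas=range(1, 21), theta_betas=range(1, 21),
                params: CRFParams = CRFParams()) -> SweepResult:
    """F1 surface over a (θα, θβ) grid.

    ``instances``: list of (proba, image01, truth_mask) triples. For every
    grid point each instance is refined and the mean F1 against ground
    truth recorded; returns the full surface and its maximizing pair.
    The conventional grid is θα, θβ ∈ 1..20 in steps of 1.
    """
    from .metrics import evaluate_masks

    theta_alphas = list(theta_alphas)
    theta_betas = list(theta_betas)
    if not instances or not theta_alphas or not theta_betas:
        raise ValueError("sweep needs a non-empty dataset and grid")
    result = SweepResult()
    for ta in theta_alphas:
        for tb in theta_betas:
            p = replace(params, theta_alpha=float(ta), theta_beta=float(tb))
            f1s = []
            for proba, image01, truth in instances:
                _, labeling = refine(proba, image01, p)
                f1s.append(evaluate_masks(labeling.astype(np.uint8), truth).f1)
            entry = {"theta_alpha": float(ta), "theta_beta": float(tb),
                     "mean_f1": float(np.mean(f1s))}
            result.surface.append(entry)
            if result.best is None or entry["mean_f1"] > result.best["mean_f1"]:
                result.best = entry
    return result
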