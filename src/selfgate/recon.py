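"""Toy motion-resolved compressed-sensing reconstruction.

A desk-scale realisation of the k-t sparse SENSE problem

    x^ = argmin_x ||F C x - y||_2^2 + lambda_r |grad_r x|_1 + lambda_c |grad_c x|_1

solved with ADMM: x is a stack of images over (respiratory bin, cardiac
bin), F is an explicit non-uniform discrete Fourier summation over each
bin's radial samples (adequate at <= 64^2 toy scale), C are simulator-
provided coil sensitivities, and the two l1 terms penalise first-order
differences along the respiratory (non-cyclic) and cardiac (cyclic, since
the heartbeat is periodic) bin axes.  Defaults follow the reference
configuration: lambda_r = lambda_c = 0.001 on unit-normalised data and 10
ADMM iterations.

The point of this module is mechanistic: binning quality measurably changes
image quality, so reconstructions binned with corrupted triggers come out
blurrier (higher RMSE, lower edge sharpness) than ground-truth-binned ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReconProblem",
    "ReconResult",
    "finite_difference",
    "finite_difference_adjoint",
    "admm_recon",
    "build_problem",
]


def finite_difference(x: np.ndarray, axis: int, cyclic: bool) -> np.ndarray:
    """First-order differences along a bin axis.

    Cyclic differences wrap around (cardiac axis); non-cyclic differences
    have length m-1 (respiratory axis).  A single bin gives a zero operator
    (empty output).
    """
    m = x.shape[axis]
    if m < 2:
        shape = list(x.shape)
        shape[axis] = 0
        return np.zeros(shape, dtype=x.dtype)
    if cyclic:
        return np.roll(x, -1, axis=axis) - x
    return np.diff(x, axis=axis)


def finite_difference_adjoint(d: np.ndarray, axis: int, cyclic: bool, m: int) -> np.ndarray:
    """Adjoint of :func:`finite_difference` for an axis of original length m."""
    shape = list(d.shape)
    shape[axis] = m
    out = np.zeros(shape, dtype=d.dtype)
    if d.shape[axis] == 0:
        return out
    if cyclic:
        return np.roll(d, 1, axis=axis) - d
    # non-cyclic: y_0 = -d_0, y_i = d_{i-1} - d_i, y_{m-1} = d_{m-2}
    sl = [slice(None)] * d.ndim
    sl_first = list(sl)
    sl_first[axis] = slice(0, m - 1)
    out[tuple(sl_first)] -= d
    sl_last = list(sl)
    sl_last[axis] = slice(1, m)
    out[tuple(sl_last)] += d
    return out


@dataclass
class ReconProblem:
    """Measured k-space per (respiratory bin, cardiac bin) plus operators.

    ``y[(r, c)]`` holds complex samples of shape (n_samples, n_coils) and
    ``traj[(r, c)]`` the matching (kx, ky) in cycles/pixel.  Every bin must
    contain at least one sample.
    """

    y: dict
    traj: dict
    coil_sens: np.ndarray  # (n_coils, N, N)
    n_resp: int
    n_card: int
    image_size: int
    lambda_r: float = 0.001
    lambda_c: float = 0.001
    iterations: int = 10
    rho: float = 1.0
    cg_iterations: int = 30

    def __post_init__(self) -> None:
        if self.lambda_r < 0 or self.lambda_c < 0:
            raise ValueError("regularisation weights must be non-negative")
        for r in range(self.n_resp):
            for c in range(self.n_card):
                if (r, c) not in self.y or self.y[(r, c)].shape[0] == 0:
                    raise ValueError(f"bin (resp={r}, card={c}) contains no samples")


@dataclass
class ReconResult:
    """Reconstructed image stack and the per-iteration objective values."""

    images: np.ndarray  # (n_resp, n_card, N, N) complex
    objective: list[float] = field(default_factory=list)
    data_fidelity: list[float] = field(default_factory=list)
    regularizer: list[float] = field(default_factory=list)


class _Operators:
    """Explicit NDFT forward/adjoint per bin, with coil sensitivities."""

    def __init__(self, p: ReconProblem):
        self.p = p
        N = p.image_size
        yy, xx = np.mgrid[0:N, 0:N].astype(float)
        px, py = xx.ravel(), yy.ravel()
        self.E = {}
        for key, (kx, ky) in p.traj.items():
            self.E[key] = np.exp(
                -2j * np.pi * (np.outer(kx.ravel(), px) + np.outer(ky.ravel(), py))
            )
        self.sens = p.coil_sens
        self.n_coils = p.coil_sens.shape[0]

    def forward(self, x: np.ndarray) -> dict:
        N = self.p.image_size
        out = {}
        for (r, c), E in self.E.items():
            xb = x[r, c].ravel()
            cx = (self.sens.reshape(self.n_coils, -1) * xb).T  # (N^2, n_coils)
            out[(r, c)] = E @ cx
        return out

    def adjoint(self, y: dict) -> np.ndarray:
        N = self.p.image_size
        x = np.zeros((self.p.n_resp, self.p.n_card, N, N), complex)
        for (r, c), E in self.E.items():
            g = E.conj().T @ y[(r, c)]  # (N^2, n_coils)
            x[r, c] = (np.conj(self.sens.reshape(self.n_coils, -1)) * g.T).sum(axis=0).reshape(N, N)
        return x

    def normal(self, x: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(x))


def _soft(z: np.ndarray, thresh: float) -> np.ndarray:
    mag = np.abs(z)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mag > 0, np.maximum(mag - thresh, 0.0) / np.where(mag > 0, mag, 1.0), 0.0)
    return z * scale


def _cg(apply_A, b: np.ndarray, x0: np.ndarray, n_iter: int, tol: float = 1e-12) -> np.ndarray:
    x = x0.copy()
    r = b - apply_A(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    b_norm = np.vdot(b, b).real
    for _ in range(n_iter):
        if rs <= tol * max(b_norm, 1e-300):
            break
        Ap = apply_A(p)
        alpha = rs / np.vdot(p, Ap).real
        x += alpha * p
        r -= alpha * Ap
        rs_new = np.vdot(r, r).real
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x


def admm_recon(p: ReconProblem) -> ReconResult:
    """Solve the binned compressed-sensing problem with ADMM.

    The data are scaled so that a quick least-squares reconstruction has
    unit maximum magnitude; the regularisation weights are therefore
    interpreted relative to unit-normalised images, and the output images
    are scaled back.  ADMM splits the two anisotropic l1 difference terms with
    auxiliary variables and complex soft-thresholding; the x-update is
    solved by warm-started conjugate gradients on the normal equations.
    With both weights zero the problem degenerates to least squares and is
    solved by plain CG (the fully sampled single-bin case then reproduces
    the inverse transform).  The per-iteration value of the objective is
    recorded.
    """
    ops = _Operators(p)
    ynorm = np.sqrt(sum(float(np.vdot(v, v).real) for v in p.y.values()))
    if ynorm == 0:
        raise ValueError("all-zero k-space data")
    y = {k: v / ynorm for k, v in p.y.items()}
    N = p.image_size
    # second normalisation stage: unit-max least-squares image, so the
    # l1 weights act on images of order one
    x0 = _cg(ops.normal, ops.adjoint(y), np.zeros((p.n_resp, p.n_card, N, N), complex), n_iter=5)
    peak = float(np.abs(x0).max())
    if peak > 0:
        y = {k: v / peak for k, v in y.items()}
        ynorm *= peak
    Aty = ops.adjoint(y)
    x = np.zeros((p.n_resp, p.n_card, N, N), complex)

    def data_terms(xx):
        fwd = ops.forward(xx)
        df = sum(float(np.vdot(fwd[k] - y[k], fwd[k] - y[k]).real) for k in y)
        dr = finite_difference(xx, axis=0, cyclic=False)
        dc = finite_difference(xx, axis=1, cyclic=True)
        reg = p.lambda_r * float(np.abs(dr).sum()) + p.lambda_c * float(np.abs(dc).sum())
        return df, reg

    result = ReconResult(images=x)

    if p.lambda_r == 0 and p.lambda_c == 0:
        for _ in range(p.iterations):
            x = _cg(ops.normal, Aty, x, n_iter=p.cg_iterations)
            df, reg = data_terms(x)
            result.data_fidelity.append(df)
            result.regularizer.append(reg)
            result.objective.append(df + reg)
        result.images = x * ynorm
        return result

    rho = p.rho
    zr = finite_difference(x, axis=0, cyclic=False)
    zc = finite_difference(x, axis=1, cyclic=True)
    ur = np.zeros_like(zr)
    uc = np.zeros_like(zc)

    def lhs(xx):
        out = ops.normal(xx)
        out += rho * finite_difference_adjoint(
            finite_difference(xx, axis=0, cyclic=False), axis=0, cyclic=False, m=p.n_resp
        )
        out += rho * finite_difference_adjoint(
            finite_difference(xx, axis=1, cyclic=True), axis=1, cyclic=True, m=p.n_card
        )
        return out

    for _ in range(p.iterations):
        rhs = Aty + rho * (
            finite_difference_adjoint(zr - ur, axis=0, cyclic=False, m=p.n_resp)
            + finite_difference_adjoint(zc - uc, axis=1, cyclic=True, m=p.n_card)
        )
        x = _cg(lhs, rhs, x, n_iter=p.cg_iterations)
        dxr = finite_difference(x, axis=0, cyclic=False)
        dxc = finite_difference(x, axis=1, cyclic=True)
        zr = _soft(dxr + ur, p.lambda_r / rho)
        zc = _soft(dxc + uc, p.lambda_c / rho)
        ur = ur + dxr - zr
        uc = uc + dxc - zc
        df, reg = data_terms(x)
        result.data_fidelity.append(df)
        result.regularizer.append(reg)
        result.objective.append(df + reg)

    result.images = x * ynorm
    return result


def build_problem(
    kspace: np.ndarray,
    kx: np.ndarray,
    ky: np.ndarray,
    resp_bins: np.ndarray,
    card_bins: np.ndarray,
    n_resp: int,
    n_card: int,
    coil_sens: np.ndarray,
    image_size: int,
    **kwargs,
) -> ReconProblem:
    """Group per-spoke radial samples into a binned reconstruction problem.

    ``kspace`` is (n_spokes, n_read, n_coils); ``resp_bins``/``card_bins``
    assign each spoke to a bin (-1 = rejected, spoke dropped).
    """
    y: dict = {}
    traj: dict = {}
    for r in range(n_resp):
        for c in range(n_card):
            sel = np.flatnonzero((resp_bins == r) & (card_bins == c))
            y[(r, c)] = kspace[sel].reshape(-1, kspace.shape[2])
            traj[(r, c)] = (kx[sel].ravel(), ky[sel].ravel())
    return ReconProblem(
        y=y,
        traj=traj,
        coil_sens=coil_sens,
        n_resp=n_resp,
        n_card=n_card,
        image_size=image_size,
        **kwargs,
    )
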