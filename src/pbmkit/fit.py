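"""Sparse Bayesian learning of binding-model parameters.

The model is fitted by minimizing the regularized least-squares objective

    F = β·E_D + Σ_g α_g·E_{w,g},
    E_D = ½ Σ_i (T_i − Y_i)²,   E_{w,g} = ½ Σ_{j∈g} w_j²,

where T_i are normalized probe intensities, Y_i the predicted occupancies,
β the noise precision, and the parameters are split into shrinkage groups
g ∈ {output (w1, b1), chemical potential μ, energy matrix E, dinucleotide
block D} with their own α_g.  Point estimates are found by resilient
backpropagation (Rprop) on the analytic gradients; every few epochs the
hyperparameters are re-estimated by the evidence approximation (MacKay
updates) with a Gauss–Newton Hessian, which drives the α of irrelevant
groups up until they are pruned — the mechanism that keeps the 16(L−1)
dinucleotide parameters from overfitting.  Multiple restarts from small
random initializations are ranked by final training error (the
objective itself is not comparable across restarts because each adapts
its own noise precision β); the two best distinct optima are reported
as the first and second motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.special import expit

from . import _encode
from .energy_model import (BindingModel, DinucCorrection, EnergyMatrix,
                           predict_intensities)
from .errors import (DegenerateInputError, DomainError, EmptyInputError,
                     FitFailureError)
from .pbm_io import ProbeTable

_ALPHA_MIN = 1e-6
_BETA_MIN = 1e-6
#: cap on the noise precision when the fit becomes noiseless (E_D -> 0)
BETA_CAP = 1e8


@dataclass
class HyperParams:
    """Shrinkage (α per group) and noise precision (β) hyperparameters."""

    beta: float = 1.0
    alpha_output: float = 0.01
    alpha_mu: float = 0.01
    alpha_energy: float = 0.01
    alpha_dinuc: Optional[float] = 0.01
    gammas: Dict[str, float] = field(default_factory=dict)

    def group_alphas(self, dependent: bool) -> Dict[str, float]:
        out = {"energy": self.alpha_energy, "mu": self.alpha_mu,
               "output": self.alpha_output}
        if dependent:
            out["dinuc"] = self.alpha_dinuc if self.alpha_dinuc is not None else 0.01
        return out


@dataclass(frozen=True)
class RpropConfig:
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_max: float = 50.0
    delta_min: float = 1e-6


@dataclass
class FitConfig:
    """Reproducible fitting configuration (all randomness from ``seed``)."""

    motif_lengths: Sequence[int] = tuple(range(7, 14))
    n_restarts: int = 5
    seed: int = 0
    max_epochs: int = 2500
    rprop: RpropConfig = field(default_factory=RpropConfig)
    hyper_update_every: int = 10
    tol: float = 1e-6
    alpha_prune: float = 1e6
    dependent: bool = False
    both_strands: bool = True
    init_scale: float = 0.1

    def __post_init__(self):
        if any(L < 2 for L in self.motif_lengths):
            raise DomainError("motif lengths must be >= 2")
        if self.n_restarts < 1:
            raise DomainError("need at least one restart")


@dataclass
class FitResult:
    """Ranked fitted models for one motif length.

    ``models[0]`` is the first motif (best final objective), ``models[1]``
    the second, after deduplication of restarts that converged to the same
    optimum (aligned energy correlation > 0.95).
    """

    models: list[BindingModel]
    training_error: list[float]          # E_D per ranked model
    objectives: list[float]              # final F per ranked model
    hyper: list[HyperParams]
    traces: list[np.ndarray]             # per-epoch objective, per ranked model
    seeds: list[int]
    motif_length: int = 0


# ---------------------------------------------------------------------------
# parameter vector layout


class _Layout:
    """Slices of the flat parameter vector [E, (D,), mu, w1, b1]."""

    def __init__(self, L: int, dependent: bool):
        self.L = L
        self.dependent = dependent
        self.n_e = 4 * L
        self.n_d = 16 * (L - 1) if dependent else 0
        self.e = slice(0, self.n_e)
        self.d = slice(self.n_e, self.n_e + self.n_d)
        self.mu = self.n_e + self.n_d
        self.w1 = self.mu + 1
        self.b1 = self.mu + 2
        self.size = self.mu + 3

    def groups(self) -> Dict[str, np.ndarray]:
        g = {"energy": np.arange(self.e.start, self.e.stop),
             "mu": np.array([self.mu]),
             "output": np.array([self.w1, self.b1])}
        if self.dependent:
            g["dinuc"] = np.arange(self.d.start, self.d.stop)
        return g

    def project_dinuc(self, theta: np.ndarray) -> np.ndarray:
        """Project the D block onto interaction-only coordinates.

        Any separable (per-base) component of an adjacent-pair block is
        exactly representable by the mononucleotide matrix plus μ, which
        makes the raw parametrization non-identifiable — and a quadratic
        penalty prefers to smear mono structure across the larger D
        block.  Fitting therefore constrains every 4×4 pair matrix to
        zero row and column means (the standard interaction coding), so
        the energy matrix carries all separable structure.  In place.
        """
        if not self.dependent:
            return theta
        C = np.eye(4) - 0.25
        D = theta[self.d].reshape(self.L - 1, 4, 4)
        theta[self.d] = np.einsum("ab,jbc,cd->jad", C, D, C).reshape(-1)
        return theta

    def pack(self, model: BindingModel) -> np.ndarray:
        theta = np.empty(self.size)
        theta[self.e] = model.energy.matrix.reshape(-1)
        if self.dependent:
            if model.dinuc is None:
                theta[self.d] = 0.0
            else:
                theta[self.d] = model.dinuc.matrix.reshape(-1)
        theta[self.mu] = model.mu
        theta[self.w1] = model.w1
        theta[self.b1] = model.b1
        return theta

    def unpack(self, theta: np.ndarray) -> BindingModel:
        E = EnergyMatrix(theta[self.e].reshape(self.L, 4).copy())
        dinuc = None
        if self.dependent:
            dinuc = DinucCorrection(theta[self.d].reshape(self.L - 1, 16).copy())
        return BindingModel(energy=E, dinuc=dinuc, mu=float(theta[self.mu]),
                            w1=float(theta[self.w1]), b1=float(theta[self.b1]))


class _Design:
    """Precomputed window index arrays and targets for one probe table.

    The map from the (E, D) parameter block to window energies is linear
    in the parameters.  For motifs up to length 10 there are at most 4^L
    ≈ 10^6 distinct windows, far fewer than windows on the array, so the
    energy of *every possible window* is tabulated each epoch (a (4,)*L
    tensor built by broadcasting) and windows are scored by table lookup;
    the gradient scatters back through a per-code bincount and axis
    reductions of the same tensor.  Longer motifs fall back to a sparse
    count matrix A (windows × parameters): E_win = A·θ_ed with the chain
    rule as the transpose product.
    """

    #: largest motif length handled by the 4^L code-table fast path
    _CODE_PATH_MAX_L = 10

    def __init__(self, probes: ProbeTable, L: int, both_strands: bool,
                 dependent: bool):
        if len(probes) == 0:
            raise EmptyInputError("no probes")
        self.T = probes.normalized_signal()
        X = probes.encoded()
        if X.shape[1] < L:
            raise DomainError("probes shorter than the motif")
        self.probe_idx, self.mono_idx, self.pair_idx = _encode.window_design(
            X, L, both_strands=both_strands)
        self.n = len(probes)
        self.layout = _Layout(L, dependent)
        lay = self.layout
        self._use_codes = L <= self._CODE_PATH_MAX_L
        if self._use_codes:
            bases = self.mono_idx - 4 * np.arange(L, dtype=np.int32)[None, :]
            powers = 4 ** np.arange(L - 1, -1, -1, dtype=np.int64)
            self.codes = (bases.astype(np.int64) * powers).sum(axis=1)
            self.A = self.AT = None
        else:
            n_win = len(self.probe_idx)
            cols = [self.mono_idx.reshape(-1)]
            rows = [np.repeat(np.arange(n_win, dtype=np.int32), L)]
            if dependent:
                cols.append(lay.n_e + self.pair_idx.reshape(-1))
                rows.append(np.repeat(np.arange(n_win, dtype=np.int32), L - 1))
            coo = sparse.coo_matrix(
                (np.ones(sum(len(c) for c in cols)),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(n_win, lay.n_e + lay.n_d))
            self.A = coo.tocsr()
            self.AT = self.A.T.tocsr()

    def _energy_table(self, theta: np.ndarray) -> np.ndarray:
        """E(S) of every possible window, shape (4,)*L, by broadcasting."""
        lay = self.layout
        L = lay.L
        E = theta[lay.e].reshape(L, 4)
        table = np.zeros((4,) * L)
        for i in range(L):
            shape = (1,) * i + (4,) + (1,) * (L - 1 - i)
            table += E[i].reshape(shape)
        if lay.dependent:
            D = theta[lay.d].reshape(L - 1, 4, 4)
            for j in range(L - 1):
                shape = (1,) * j + (4, 4) + (1,) * (L - 2 - j)
                table += D[j].reshape(shape)
        return table

    def _window_energies(self, theta: np.ndarray) -> np.ndarray:
        lay = self.layout
        if self._use_codes:
            return self._energy_table(theta).reshape(-1)[self.codes]
        return self.A @ theta[:lay.n_e + lay.n_d]

    def forward(self, theta: np.ndarray):
        lay = self.layout
        P = expit(theta[lay.mu] - self._window_energies(theta))
        S = np.bincount(self.probe_idx, weights=P, minlength=self.n)
        Y = theta[lay.w1] * S + theta[lay.b1]
        return P, S, Y

    def alpha_vector(self, hyper: HyperParams) -> np.ndarray:
        lay = self.layout
        a = np.empty(lay.size)
        for name, idx in lay.groups().items():
            a[idx] = hyper.group_alphas(lay.dependent)[name]
        return a

    def objective_parts(self, theta: np.ndarray, hyper: HyperParams):
        lay = self.layout
        _, _, Y = self.forward(theta)
        r = Y - self.T
        e_d = 0.5 * float(r @ r)
        reg = 0.0
        alphas = hyper.group_alphas(lay.dependent)
        for name, idx in lay.groups().items():
            reg += alphas[name] * 0.5 * float(theta[idx] @ theta[idx])
        return hyper.beta * e_d + reg, e_d

    def gradient(self, theta: np.ndarray, hyper: HyperParams,
                 state: Optional[tuple] = None):
        """Analytic ∂F/∂θ, chained through the Fermi–Dirac window sums.

        ``state`` may carry a precomputed ``(P, S, Y)`` from
        :meth:`forward` at the same θ to avoid a second pass.
        """
        lay = self.layout
        P, S, Y = state if state is not None else self.forward(theta)
        r = Y - self.T
        beta, w1 = hyper.beta, theta[lay.w1]
        grad = self.alpha_vector(hyper) * theta        # regularization term
        # dF/dE_win per window; dP/dE_win = -P(1-P)
        g_win = -beta * w1 * r[self.probe_idx] * P * (1.0 - P)
        L = lay.L
        if self._use_codes:
            g_code = np.bincount(self.codes, weights=g_win,
                                 minlength=4 ** L).reshape((4,) * L)
            ge = np.empty((L, 4))
            for i in range(L):
                axes = tuple(a for a in range(L) if a != i)
                ge[i] = g_code.sum(axis=axes)
            grad[lay.e] += ge.reshape(-1)
            if lay.dependent:
                gd = np.empty((L - 1, 16))
                for j in range(L - 1):
                    axes = tuple(a for a in range(L) if a not in (j, j + 1))
                    gd[j] = g_code.sum(axis=axes).reshape(-1)
                grad[lay.d] += gd.reshape(-1)
        else:
            grad[:lay.n_e + lay.n_d] += self.AT @ g_win
        grad[lay.mu] += -float(g_win.sum())            # dP/dmu = +P(1-P)
        grad[lay.w1] += beta * float(r @ S)
        grad[lay.b1] += beta * float(r.sum())
        return grad, r, P, S

    def _jacobian_indices(self):
        """Flat (probe, parameter) scatter indices, built once per design."""
        if getattr(self, "_jidx", None) is None:
            lay = self.layout
            npar = lay.size
            base = self.probe_idx.astype(np.int64) * npar
            jm = (base[:, None] + self.mono_idx).reshape(-1)
            jp = None
            if lay.dependent:
                jp = (base[:, None] + (lay.d.start + self.pair_idx)).reshape(-1)
            self._jidx = (jm, jp)
        return self._jidx

    def jacobian(self, theta: np.ndarray):
        """J[i, p] = ∂Y_i/∂θ_p (Gauss–Newton building block)."""
        lay = self.layout
        P, S, _ = self.forward(theta)
        q = P * (1.0 - P)
        w1 = theta[lay.w1]
        npar = lay.size
        wq = -w1 * q
        L = lay.L
        jm, jp = self._jacobian_indices()
        flat = np.bincount(jm, weights=np.repeat(wq, L),
                           minlength=self.n * npar)
        if lay.dependent:
            flat += np.bincount(jp, weights=np.repeat(wq, L - 1),
                                minlength=self.n * npar)
        J = flat.reshape(self.n, npar)
        J[:, lay.mu] = w1 * np.bincount(self.probe_idx, weights=q,
                                        minlength=self.n)
        J[:, lay.w1] = S
        J[:, lay.b1] = 1.0
        return J


# ---------------------------------------------------------------------------
# public single-step operations (wrappers over the design)


def _design_for(model: BindingModel, probes: ProbeTable,
                both_strands: bool = True) -> _Design:
    return _Design(probes, model.L, both_strands, model.dependent)


def objective(model: BindingModel, probes: ProbeTable, hyper: HyperParams,
              both_strands: bool = True) -> float:
    """F = β·E_D + Σ_g α_g·E_{w,g} for the model on the probe table."""
    design = _design_for(model, probes, both_strands)
    theta = design.layout.pack(model)
    f, _ = design.objective_parts(theta, hyper)
    return f


def training_error(model: BindingModel, probes: ProbeTable,
                   both_strands: bool = True) -> float:
    """E_D = ½ Σ (T_i − Y_i)² against normalized intensities."""
    design = _design_for(model, probes, both_strands)
    theta = design.layout.pack(model)
    _, e_d = design.objective_parts(theta, HyperParams())
    return e_d


def gradients(model: BindingModel, probes: ProbeTable, hyper: HyperParams,
              both_strands: bool = True) -> Dict[str, np.ndarray]:
    """Analytic gradients of F per parameter block."""
    design = _design_for(model, probes, both_strands)
    lay = design.layout
    theta = lay.pack(model)
    g, _, _, _ = design.gradient(theta, hyper)
    out = {"E": g[lay.e].reshape(lay.L, 4),
           "mu": float(g[lay.mu]), "w1": float(g[lay.w1]),
           "b1": float(g[lay.b1])}
    if lay.dependent:
        out["D"] = g[lay.d].reshape(lay.L - 1, 16)
    return out


@dataclass
class RpropState:
    """Per-parameter step sizes and sign memory for Rprop."""

    delta: np.ndarray
    prev_grad: np.ndarray
    prev_step: np.ndarray

    @classmethod
    def initial(cls, n: int, cfg: RpropConfig) -> "RpropState":
        return cls(delta=np.full(n, cfg.delta0),
                   prev_grad=np.zeros(n), prev_step=np.zeros(n))


def rprop_step(params: np.ndarray, grads: np.ndarray, state: RpropState,
               cfg: RpropConfig = RpropConfig()) -> np.ndarray:
    """One resilient-backpropagation update (with weight backtracking).

    Only the gradient sign is used: the per-parameter step grows by
    ``eta_plus`` when the sign repeats, shrinks by ``eta_minus`` on a sign
    flip (and the previous move is retracted), and is clamped to
    [delta_min, delta_max].  Updates ``params`` and ``state`` in place and
    returns ``params``.
    """
    sign_change = grads * state.prev_grad
    agree = sign_change > 0
    flip = sign_change < 0
    state.delta[agree] = np.minimum(state.delta[agree] * cfg.eta_plus,
                                    cfg.delta_max)
    state.delta[flip] = np.maximum(state.delta[flip] * cfg.eta_minus,
                                   cfg.delta_min)
    step = -np.sign(grads) * state.delta
    step[flip] = -state.prev_step[flip]        # retract the last move
    params += step
    state.prev_step = np.where(flip, 0.0, step)
    state.prev_grad = np.where(flip, 0.0, grads)
    return params


def update_hyperparameters(model: BindingModel, probes: ProbeTable,
                           hyper: HyperParams, alpha_prune: float = 1e6,
                           both_strands: bool = True) -> HyperParams:
    """Evidence-approximation (MacKay) update of all α groups and β."""
    design = _design_for(model, probes, both_strands)
    theta = design.layout.pack(model)
    new, _ = _update_hyper(design, theta, hyper, alpha_prune,
                           frozen=np.zeros(design.layout.size, bool))
    return new


def _update_hyper(design: _Design, theta: np.ndarray, hyper: HyperParams,
                  alpha_prune: float, frozen: np.ndarray):
    """Core MacKay update; returns (new HyperParams, frozen mask)."""
    lay = design.layout
    J = design.jacobian(theta)
    alpha_vec = design.alpha_vector(hyper)
    active = ~frozen
    Ja = J[:, active]
    H = hyper.beta * (Ja.T @ Ja) + np.diag(alpha_vec[active])
    try:
        Hinv_diag = np.diag(np.linalg.inv(H))
    except np.linalg.LinAlgError:
        Hinv_diag = np.diag(np.linalg.pinv(H))
    diag_full = np.zeros(lay.size)
    diag_full[active] = Hinv_diag
    _, _, Y = design.forward(theta)
    r = Y - design.T
    e_d = 0.5 * float(r @ r)
    alphas = hyper.group_alphas(lay.dependent)
    new_alphas: Dict[str, float] = {}
    gammas: Dict[str, float] = {}
    gamma_total = 0.0
    for name, idx in lay.groups().items():
        act = idx[active[idx]]
        n_g = len(act)
        if n_g == 0:
            gammas[name] = 0.0
            new_alphas[name] = alpha_prune
            continue
        gamma = n_g - alphas[name] * float(diag_full[act].sum())
        gamma = float(np.clip(gamma, 0.0, n_g))
        gammas[name] = gamma
        gamma_total += gamma
        e_w = 0.5 * float(theta[act] @ theta[act])
        if e_w <= 0.0:
            new_alphas[name] = alpha_prune
        else:
            new_alphas[name] = float(np.clip(gamma / (2.0 * e_w),
                                             _ALPHA_MIN, alpha_prune))
    if e_d <= 0.0:
        beta = BETA_CAP
    else:
        beta = float(np.clip((design.n - gamma_total) / (2.0 * e_d),
                             _BETA_MIN, BETA_CAP))
    new = HyperParams(
        beta=beta,
        alpha_output=new_alphas["output"],
        alpha_mu=new_alphas["mu"],
        alpha_energy=new_alphas["energy"],
        alpha_dinuc=new_alphas.get("dinuc"),
        gammas=gammas,
    )
    # groups whose alpha hit the prune threshold are frozen at zero
    for name, idx in lay.groups().items():
        if new_alphas[name] >= alpha_prune:
            frozen = frozen.copy()
            frozen[idx] = True
            theta[idx] = 0.0
    return new, frozen


# ---------------------------------------------------------------------------
# full fit


def _init_theta(lay: _Layout, rng: np.random.Generator,
                scale: float) -> np.ndarray:
    theta = np.zeros(lay.size)
    theta[lay.e] = rng.uniform(-scale, scale, lay.n_e)
    if lay.dependent:
        theta[lay.d] = rng.uniform(-scale, scale, lay.n_d)
    theta[lay.mu] = 0.0
    theta[lay.w1] = 1.0
    theta[lay.b1] = 0.0
    return theta


def _run_restart(design: _Design, config: FitConfig, seed: int):
    lay = design.layout
    rng = np.random.default_rng(seed)
    theta = lay.project_dinuc(_init_theta(lay, rng, config.init_scale))
    hyper = HyperParams()
    state = RpropState.initial(lay.size, config.rprop)
    frozen = np.zeros(lay.size, bool)
    trace = []
    prev_ed = None
    calm = 0
    for epoch in range(config.max_epochs):
        fwd = design.forward(theta)
        _, _, Y = fwd
        r = Y - design.T
        e_d = 0.5 * float(r @ r)
        reg = 0.5 * float((design.alpha_vector(hyper) * theta) @ theta)
        f = hyper.beta * e_d + reg
        trace.append(f)
        if not np.isfinite(f):
            return None, hyper, np.array(trace)
        # convergence is judged on E_D: unlike F it is comparable across
        # hyperparameter updates, and Rprop stalls only transiently, so a
        # sustained streak of sub-tolerance changes is required
        if (prev_ed is not None
                and abs(e_d - prev_ed) <= config.tol * max(1.0, prev_ed)):
            calm += 1
            if calm >= 10:
                break
        else:
            calm = 0
        prev_ed = e_d
        grad, _, _, _ = design.gradient(theta, hyper, state=fwd)
        lay.project_dinuc(grad)        # move only within identifiable space
        grad[frozen] = 0.0
        rprop_step(theta, grad, state, config.rprop)
        lay.project_dinuc(theta)
        theta[frozen] = 0.0
        if (epoch + 1) % config.hyper_update_every == 0:
            hyper, frozen = _update_hyper(design, theta, hyper,
                                          config.alpha_prune, frozen)
            # step-size sign memory is stale under the rescaled objective
            state.prev_grad[:] = 0.0
    return theta, hyper, np.array(trace)


def aligned_energy_correlation(a: EnergyMatrix, b: EnergyMatrix,
                               max_shift: int = 3) -> float:
    """Best Pearson correlation between two energy matrices over window
    phase (±max_shift) and strand, after per-position centering.

    Per-position centering removes the gauge freedom of the model: adding
    a constant to all four energies at one position only shifts μ.
    """
    def centered(M):
        return M - M.mean(axis=1, keepdims=True)

    A = centered(a.matrix)
    candidates = [centered(b.matrix), centered(b.matrix[::-1, ::-1])]
    best = -1.0
    for B in candidates:
        for shift in range(-max_shift, max_shift + 1):
            lo_a, hi_a = max(0, shift), min(A.shape[0], B.shape[0] + shift)
            if hi_a - lo_a < 2:
                continue
            sub_a = A[lo_a:hi_a].reshape(-1)
            sub_b = B[lo_a - shift:hi_a - shift].reshape(-1)
            if sub_a.std() == 0 or sub_b.std() == 0:
                continue
            best = max(best, float(np.corrcoef(sub_a, sub_b)[0, 1]))
    return best


def fit(probes: ProbeTable, config: FitConfig,
        motif_length: Optional[int] = None) -> FitResult:
    """Fit a binding model of one motif length with restarts.

    Deterministic given ``config.seed``: restart r uses seed
    ``config.seed + r``.  Restarts are ranked by final training error
    E_D (β differs per restart, so objectives are not comparable); optima
    whose aligned energy correlation exceeds 0.95 are collapsed so the
    first and second motif are genuinely distinct.
    """
    L = motif_length if motif_length is not None else config.motif_lengths[0]
    design = _Design(probes, L, config.both_strands, config.dependent)
    runs = []
    traces = []
    for r in range(config.n_restarts):
        seed = int(config.seed) + r
        theta, hyper, trace = _run_restart(design, config, seed)
        traces.append(trace)
        if theta is None:
            continue
        f, e_d = design.objective_parts(theta, hyper)
        if not np.isfinite(f):
            continue
        runs.append((f, e_d, theta, hyper, trace, seed))
    if not runs:
        raise FitFailureError("all restarts diverged", traces=traces)
    runs.sort(key=lambda t: t[1])      # by E_D; β-scaled F is incomparable
    models, errs, objs, hypers, kept_traces, seeds = [], [], [], [], [], []
    for f, e_d, theta, hyper, trace, seed in runs:
        model = design.layout.unpack(theta)
        duplicate = any(
            aligned_energy_correlation(model.energy, m.energy) > 0.95
            for m in models)
        if duplicate:
            continue
        models.append(model)
        errs.append(e_d)
        objs.append(f)
        hypers.append(hyper)
        kept_traces.append(trace)
        seeds.append(seed)
    return FitResult(models=models, training_error=errs, objectives=objs,
                     hyper=hypers, traces=kept_traces, seeds=seeds,
                     motif_length=L)


def fit_scan(probes: ProbeTable, config: FitConfig) -> Dict[int, FitResult]:
    """Fit every motif length in ``config.motif_lengths``."""
    return {L: fit(probes, config, motif_length=L)
            for L in config.motif_lengths}


def select_model(results: Mapping[int, FitResult], heldout: ProbeTable,
                 both_strands: bool = True):
    """Pick the candidate with the highest held-out prediction correlation.

    Every ranked model of every motif length is scored by the Pearson
    correlation between its predicted intensities and the held-out
    normalized intensities; ties break toward smaller length, then lower
    rank.  Returns ``(model, motif_length, correlation)``.
    """
    if len(heldout) == 0:
        raise EmptyInputError("empty held-out table")
    T = heldout.normalized_signal()
    best = None
    for L in sorted(results):
        for rank, model in enumerate(results[L].models):
            Y = predict_intensities(model, heldout, both_strands)
            if Y.std() == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(Y, T)[0, 1])
            key = (-corr, L, rank)
            if best is None or key < best[0]:
                best = (key, model, L, corr)
    return best[1], best[2], best[3]


def heldout_correlation(model: BindingModel, heldout: ProbeTable,
                        both_strands: bool = True) -> float:
    """Pearson correlation between predictions and held-out intensities."""
    Y = predict_intensities(model, heldout, both_strands)
    T = heldout.normalized_signal()
    if Y.std() == 0:
        return 0.0
    return float(np.corrcoef(Y, T)[0, 1])
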