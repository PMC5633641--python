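"""Energy minimisation: limited-memory BFGS and Powell-Beale restarted
conjugate gradient, with atom freezing and an average-per-atom-gradient
convergence test.

The default method follows system size: L-BFGS for large (protein-sized)
systems, conjugate gradient for small molecules.  Convergence is declared
when the mean per-atom gradient norm over the free atoms drops below
``grad_tol`` (kcal/mol/A); an RMS-gradient test can be selected instead.
Line searches: Armijo backtracking with a curvature check for L-BFGS, a
safeguarded secant search on the directional derivative (exact for
quadratics after one secant step) for CG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import NonbondedSettings, ParameterSet, energy_and_gradient
from .molsys import MolecularSystem, Topology

__all__ = [
    "MinimizerOptions", "MinimizationResult", "minimize_vector", "minimize",
    "minimize_complex", "rmsd_heavy",
]


@dataclass
class MinimizerOptions:
    method: str = "auto"            # lbfgs | cg_powell_beale | auto
    grad_tol: float = 0.5           # (kcal/mol)/A, mean per-atom gradient norm
    max_iter: int = 2000
    history: int = 10               # L-BFGS memory
    frozen: frozenset[int] = field(default_factory=frozenset)
    grad_measure: str = "mean"      # mean | rms per-atom gradient norm
    size_switch: int = 400          # auto: > this many atoms -> lbfgs


@dataclass
class MinimizationResult:
    coords: np.ndarray
    energy: float
    avg_grad: float
    iterations: int
    converged: bool
    message: str = ""
    restarts: int = 0   # Powell restarts taken (CG only)


def _grad_measure(g: np.ndarray, free: np.ndarray, mode: str) -> float:
    """Aggregate per-atom gradient norms; vectors whose length is not a
    multiple of 3 are treated as a single 'atom'."""
    if g.size % 3 == 0 and g.size >= 3:
        norms = np.linalg.norm(g.reshape(-1, 3), axis=1)
        fa = free.reshape(-1, 3)[:, 0]
        norms = norms[fa]
    else:
        norms = np.array([np.linalg.norm(g[free])])
    if norms.size == 0:
        return 0.0
    if mode == "rms":
        return float(np.sqrt(np.mean(norms ** 2)))
    return float(np.mean(norms))


def minimize_vector(fun, x0: np.ndarray, options: MinimizerOptions | None = None,
                    frozen_coords: np.ndarray | None = None) -> MinimizationResult:
    """Minimise ``fun(x) -> (f, g)`` over a flat coordinate vector.

    ``frozen_coords`` is a boolean mask of coordinates held bit-identical to
    their input values.  Energy is non-increasing over accepted steps; a
    failed line search terminates with ``converged=False`` and a diagnostic
    rather than raising.
    """
    if options is None:
        options = MinimizerOptions()
    x = np.asarray(x0, float).copy()
    free = np.ones(x.size, dtype=bool) if frozen_coords is None else ~np.asarray(frozen_coords)
    if not free.any():
        raise ValueError("no free coordinates to optimise")

    def feval(xv):
        f, g = fun(xv)
        g = np.asarray(g, float).ravel().copy()
        g[~free] = 0.0
        return float(f), g

    method = options.method
    if method == "auto":
        method = "lbfgs" if x.size // 3 > options.size_switch else "cg_powell_beale"
    if method == "lbfgs":
        return _lbfgs(feval, x, free, options)
    if method == "cg_powell_beale":
        return _cg_powell_beale(feval, x, free, options)
    raise ValueError(f"unknown method {options.method!r}")


def _result(x, f, g, free, it, converged, options, message="", restarts=0):
    return MinimizationResult(coords=x, energy=f,
                              avg_grad=_grad_measure(g, free, options.grad_measure),
                              iterations=it, converged=converged, message=message,
                              restarts=restarts)


def _lbfgs(feval, x, free, options) -> MinimizationResult:
    m = max(1, options.history)
    s_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []
    f, g = feval(x)
    for it in range(options.max_iter):
        if _grad_measure(g, free, options.grad_measure) < options.grad_tol:
            return _result(x, f, g, free, it, True, options)
        # two-loop recursion
        q = g.copy()
        alphas = []
        for s, y in zip(reversed(s_list), reversed(y_list)):
            rho = 1.0 / float(np.dot(y, s))
            a = rho * float(np.dot(s, q))
            alphas.append((a, rho))
            q -= a * y
        if y_list:
            ylast, slast = y_list[-1], s_list[-1]
            q *= float(np.dot(slast, ylast) / np.dot(ylast, ylast))
        for (a, rho), s, y in zip(reversed(alphas), s_list, y_list):
            b = rho * float(np.dot(y, q))
            q += (a - b) * s
        d = -q
        d[~free] = 0.0
        if float(np.dot(d, g)) >= 0.0:  # not a descent direction: reset
            d = -g
            s_list, y_list = [], []
        step = _armijo_wolfe(feval, x, f, g, d)
        if step is None:
            return _result(x, f, g, free, it, False, options,
                           "line search failed (max backtracks)")
        alpha, xn, fn, gn = step
        s_vec = xn - x
        y_vec = gn - g
        if float(np.dot(s_vec, y_vec)) > 1e-12:
            s_list.append(s_vec)
            y_list.append(y_vec)
            if len(s_list) > m:
                s_list.pop(0)
                y_list.pop(0)
        x, f, g = xn, fn, gn
    return _result(x, f, g, free, options.max_iter, False, options,
                   "max iterations reached")


def _armijo_wolfe(feval, x, f, g, d, c1=1e-4, c2=0.9, max_backtracks=40):
    """Backtracking line search: Armijo decrease, then try to also satisfy
    the curvature condition by one expansion pass."""
    g0d = float(np.dot(g, d))
    alpha = 1.0
    for _ in range(max_backtracks):
        xn = x + alpha * d
        fn, gn = feval(xn)
        if np.isfinite(fn) and fn <= f + c1 * alpha * g0d:
            if float(np.dot(gn, d)) >= c2 * g0d or alpha >= 1.0:
                return alpha, xn, fn, gn
            alpha *= 2.0  # curvature too negative: expand once
            xe = x + alpha * d
            fe, ge = feval(xe)
            if np.isfinite(fe) and fe <= f + c1 * alpha * g0d:
                return alpha, xe, fe, ge
            return alpha / 2.0, xn, fn, gn
        alpha *= 0.5
    return None


def _secant_line_search(feval, x, f, g, d, max_iter=25, c1=1e-4):
    """Near-exact line search: expand until the directional derivative turns
    positive (or the energy rises), then secant/bisection on phi'(alpha).
    Exact after one secant step on quadratics.  Returns the best Armijo-
    acceptable point found."""
    phi0p = float(np.dot(g, d))
    if phi0p >= 0:
        return None
    best = None

    def probe(alpha):
        nonlocal best
        xn = x + alpha * d
        fn, gn = feval(xn)
        phip = float(np.dot(gn, d)) if np.all(np.isfinite(gn)) else math.inf
        if np.isfinite(fn) and fn <= f + c1 * alpha * phi0p:
            if best is None or fn < best[2]:
                best = (alpha, xn, fn, gn)
        return fn, phip

    # expansion phase: march out until the energy rises or phi' turns positive
    a_lo, p_lo, f_lo = 0.0, phi0p, f
    alpha = 1.0
    a_hi = p_hi = None
    for _ in range(max_iter):
        fn, phip = probe(alpha)
        if not np.isfinite(fn) or fn > f + c1 * alpha * phi0p or fn >= f_lo:
            a_hi, p_hi = alpha, (phip if np.isfinite(phip) else None)
            break
        if phip >= 0:
            a_hi, p_hi = alpha, phip
            break
        a_lo, p_lo, f_lo = alpha, phip, fn
        alpha *= 2.0
    if a_hi is None:
        return best
    # zoom: keep a_lo the best acceptable point, shrink towards the minimum
    for _ in range(max_iter):
        if p_hi is not None and p_lo is not None and p_hi != p_lo and a_hi != a_lo:
            a_new = a_hi - p_hi * (a_hi - a_lo) / (p_hi - p_lo)
            lo, hi = min(a_lo, a_hi), max(a_lo, a_hi)
            margin = 0.05 * (hi - lo)
            if not lo + margin < a_new < hi - margin:
                a_new = 0.5 * (a_lo + a_hi)   # secant stalling: bisect
        else:
            a_new = 0.5 * (a_lo + a_hi)
        if abs(a_new - a_lo) < 1e-14 * max(1.0, abs(a_lo)):
            break
        fn, phip = probe(a_new)
        if not np.isfinite(fn) or fn > f + c1 * a_new * phi0p or fn >= f_lo:
            a_hi, p_hi = a_new, (phip if np.isfinite(phip) else None)
        else:
            if abs(phip) <= 1e-10 * abs(phi0p):
                break
            if p_hi is not None and phip * (a_hi - a_lo) >= 0:
                a_hi, p_hi = a_lo, p_lo
            a_lo, p_lo, f_lo = a_new, phip, fn
    return best


def _cg_powell_beale(feval, x, free, options) -> MinimizationResult:
    """Conjugate gradient with Powell's restart criterion and Beale's
    three-term direction update."""
    f, g = feval(x)
    d = -g                        # the initial direction is the restart step
    d_restart = None              # direction at the last restart (Beale term)
    y_restart = None              # gradient change across the restart step
    pending_restart_pair = (d,)
    n_restarts = 0
    steps_since_restart = 0
    for it in range(options.max_iter):
        if _grad_measure(g, free, options.grad_measure) < options.grad_tol:
            return _result(x, f, g, free, it, True, options, restarts=n_restarts)
        step = _secant_line_search(feval, x, f, g, d)
        if step is None:
            if np.allclose(d, -g):
                return _result(x, f, g, free, it, False, options,
                               "line search failed (max backtracks)",
                               restarts=n_restarts)
            d = -g  # steepest-descent restart, retry
            pending_restart_pair = (d,)
            steps_since_restart = 0
            continue
        _alpha, xn, fn, gn = step
        steps_since_restart += 1
        if pending_restart_pair is not None:
            d_restart, y_restart = pending_restart_pair[0], gn - g
            pending_restart_pair = None
        # Powell restart test: loss of conjugacy
        restart = abs(float(np.dot(gn, g))) >= 0.2 * float(np.dot(gn, gn))
        if restart:
            n_restarts += 1
            dn = -gn
            pending_restart_pair = (dn,)
            steps_since_restart = 0
        else:
            y = gn - g
            denom = float(np.dot(d, y))
            beta = float(np.dot(gn, y)) / denom if abs(denom) > 1e-30 else 0.0
            dn = -gn + beta * d
            # Beale's third term only once the restart direction is older
            # than the previous step (otherwise it duplicates beta * d)
            if steps_since_restart >= 2 and d_restart is not None and y_restart is not None:
                denr = float(np.dot(d_restart, y_restart))
                if abs(denr) > 1e-30:
                    dn += (float(np.dot(gn, y_restart)) / denr) * d_restart
            if float(np.dot(dn, gn)) >= 0.0:
                dn = -gn
                pending_restart_pair = (dn,)
                steps_since_restart = 0
        x, f, g, d = xn, fn, gn, dn
        d[~free] = 0.0
    return _result(x, f, g, free, options.max_iter, False, options,
                   "max iterations reached", restarts=n_restarts)


# -- system-level wrappers ----------------------------------------------------

def minimize(system: MolecularSystem, topology: Topology, params: ParameterSet,
             settings: NonbondedSettings | None = None,
             options: MinimizerOptions | None = None) -> MinimizationResult:
    """Minimise the force-field energy of a system.  Frozen atoms keep their
    input coordinates bit-identical.  The input system is not mutated;
    apply ``system.set_coords(result.coords)`` to accept the result."""
    if options is None:
        options = MinimizerOptions()
    x0 = system.coords().ravel()
    n = len(system.atoms)
    frozen_mask = np.zeros(3 * n, dtype=bool)
    for i in options.frozen:
        frozen_mask[3 * i: 3 * i + 3] = True

    def fun(xflat):
        rep, grad = energy_and_gradient(system, topology, params, settings,
                                        coords=xflat.reshape(n, 3))
        return rep.total, grad.ravel()

    res = minimize_vector(fun, x0, options, frozen_coords=frozen_mask)
    res.coords = res.coords.reshape(n, 3)
    if options.frozen:
        res.coords[sorted(options.frozen)] = system.coords()[sorted(options.frozen)]
    return res


def minimize_complex(system: MolecularSystem, ligand_selection: set[int],
                     flexible_residues: set[int] | None = None,
                     topology: Topology | None = None,
                     params: ParameterSet | None = None,
                     settings: NonbondedSettings | None = None,
                     options: MinimizerOptions | None = None) -> MinimizationResult:
    """Partial optimisation of a complex: the ligand is fully flexible, and
    protein atoms are frozen except those in ``flexible_residues``."""
    if options is None:
        options = MinimizerOptions()
    flexible_residues = flexible_residues or set()
    free = set(ligand_selection)
    for ridx in flexible_residues:
        free.update(system.residues[ridx].atom_indices)
    frozen = frozenset(range(len(system.atoms))) - free
    if not free:
        raise ValueError("empty free set: nothing to optimise")
    options = MinimizerOptions(**{**options.__dict__, "frozen": frozen})
    if topology is None:
        from .molsys import perceive_topology
        topology = perceive_topology(system)
    return minimize(system, topology, params, settings, options)


def rmsd_heavy(reference: MolecularSystem, optimised: MolecularSystem | np.ndarray) -> float:
    """Plain (non-superposed) RMSD over non-hydrogen atoms, Angstrom."""
    ref = reference.coords()
    opt = optimised if isinstance(optimised, np.ndarray) else optimised.coords()
    if ref.shape != opt.shape:
        raise ValueError("atom-count mismatch between reference and optimised system")
    heavy = np.array([a.element != "H" for a in reference.atoms])
    if not heavy.any():
        raise ValueError("no heavy atoms")
    d = ref[heavy] - opt[heavy]
    return float(math.sqrt(np.mean(np.sum(d * d, axis=1))))
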