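"""Master equation for parallel assembly of small rings (capsomers).

Mean-field rate equations for the populations ``nu_n(t)`` of clusters of
size ``n`` (``1 <= n <= n_f``, ring size ``n_f``) under

* pairwise coagulation at rate ``a`` per cluster pair per unit time
  (size-independent),
* fragmentation of open chains at rate ``b`` per bond: a size-``n`` chain
  (``n < n_f``) carries ``n - 1`` bonds and decays to fragments ``(k,
  n-k)``; size-``k`` daughters are produced at rate ``2 b`` per chain for
  every ``k < n`` (multiplicity coefficient ``d_nk = 2`` for ``k < n``
  and ``d_nn = -(n-1)``),
* irreversible ring closure: completed rings of size ``n_f`` neither
  grow nor decay.

Association channels use the standard symmetrised mass-action convention
(factor 1/2 on like-size pair sums), under which the total monomer mass
``sum_n n nu_n = N`` is conserved identically.

The module provides the deterministic integrator, an exact-stochastic
(Gillespie) oracle of the same reaction network, the joint least-squares
fit of association rates with a shared bond dissociation rate — exposed
statsmodels-style as the `RingAssemblyME` model whose ``fit`` returns a
`RingMEFitResults` — and the conversion between the per-pair rate ``a``
and a molar association rate constant via ``a = k_a c / N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

NS_PER_S = 1e9


class MasterEquationError(ValueError):
    pass


@dataclass(frozen=True)
class MEParams:
    """Rates and system constants of the ring-assembly network."""

    a: float      # association rate per cluster pair, ns^-1
    b: float      # dissociation rate per bond, ns^-1
    n_f: int = 6  # ring size (6 hexamer, 5 pentamer)
    N: int = 60   # total monomers

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise MasterEquationError("rates must be non-negative")
        if self.n_f < 2 or self.N < 1:
            raise MasterEquationError("need n_f >= 2 and N >= 1")


def decay_coefficient(n: int, k: int, n_f: int) -> float:
    """Multiplicity d_nk of the decay channel size n -> daughter size k.

    ``d_nk = 2`` for every daughter ``k < n`` (the two chain bonds at
    positions k and n-k each yield one size-k fragment, and the middle
    bond of an even chain yields two), and ``d_nn = -(n-1)`` is the total
    decay rate multiplier (one bond per chain link).  Completed rings
    (``n = n_f``) have no decay channel.
    """
    if n >= n_f:
        raise MasterEquationError(
            f"size-{n_f} rings are closed irreversibly and have no decay terms"
        )
    if not 1 <= k <= n:
        raise MasterEquationError(f"daughter size {k} outside 1..{n}")
    if k == n:
        return -(n - 1)
    return 2.0


def me_rhs(nu: np.ndarray, params: MEParams) -> np.ndarray:
    """Time derivative of the populations under the master equation."""
    nu = np.asarray(nu, dtype=float)
    nf = params.n_f
    if nu.shape != (nf,):
        raise MasterEquationError(f"nu must have length n_f={nf}")
    if nu.min() < -1e-8 * max(1.0, params.N):
        raise MasterEquationError(f"negative population {nu.min()}")
    a, b = params.a, params.b
    dnu = np.zeros(nf)
    # association: symmetrised gain, plain-sum loss (self-pair consumption
    # of two clusters is exactly the k = n term of the loss sum)
    for n in range(2, nf + 1):
        gain = 0.0
        for k in range(1, n):
            gain += nu[k - 1] * nu[n - k - 1]
        dnu[n - 1] += 0.5 * a * gain
    for n in range(1, nf):
        dnu[n - 1] -= a * nu[n - 1] * nu[: nf - n].sum()
    # fragmentation of open chains; rings (n = nf) are absorbing
    for n in range(2, nf):
        dnu[n - 1] -= b * (n - 1) * nu[n - 1]
        dnu[: n - 1] += 2.0 * b * nu[n - 1]
    return dnu


@dataclass
class METrajectory:
    """Deterministic (or ensemble-mean) population curves."""

    t_grid: np.ndarray
    nu: np.ndarray  # (len(t_grid), n_f)
    params: MEParams | None = None

    @property
    def n_f(self) -> int:
        return self.nu.shape[1]

    def mass(self) -> np.ndarray:
        n = np.arange(1, self.n_f + 1)
        return self.nu @ n

    def validate(self, tol: float = 1e-6) -> None:
        m = self.mass()
        if np.abs(m - m[0]).max() > tol * m[0]:
            raise MasterEquationError("mass not conserved along trajectory")
        if np.any(np.diff(self.nu[:, -1]) < -tol * max(1.0, m[0])):
            raise MasterEquationError("ring population must be nondecreasing")
        if self.nu.min() < -tol * max(1.0, m[0]):
            raise MasterEquationError("negative populations")


def integrate_me(
    params: MEParams,
    nu0: np.ndarray,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> METrajectory:
    """Integrate the master equation on ``t_grid`` (stiff-capable LSODA)."""
    nu0 = np.asarray(nu0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if nu0.shape != (params.n_f,):
        raise MasterEquationError("nu0 must have length n_f")
    n = np.arange(1, params.n_f + 1)
    if abs(float(nu0 @ n) - params.N) > 1e-9 * params.N:
        raise MasterEquationError(
            f"initial condition carries mass {float(nu0 @ n)} != N={params.N}"
        )
    if np.any(np.diff(t_grid) <= 0):
        raise MasterEquationError("t_grid must be strictly increasing")

    sol = solve_ivp(
        lambda _, y: me_rhs(np.maximum(y, 0.0), params),
        (t_grid[0], t_grid[-1]),
        nu0,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise MasterEquationError(f"integrator failed: {sol.message}")
    nu = sol.y.T
    if nu.min() < -1e-10 * max(1.0, params.N):
        raise MasterEquationError(f"integration produced nu_min={nu.min()}")
    return METrajectory(t_grid=t_grid, nu=np.maximum(nu, 0.0), params=params)


# ---------------------------------------------------------------------------
# stochastic oracle
# ---------------------------------------------------------------------------

def gillespie_ring_network(
    params: MEParams,
    rng: np.random.Generator,
    t_grid: np.ndarray,
) -> METrajectory:
    """Exact stochastic simulation of the same reaction network.

    Coagulation of an (unordered) cluster pair of sizes ``(k, l)`` fires
    with propensity ``a nu_k nu_l`` (``a nu_k (nu_k - 1) / 2`` for like
    sizes); a size-``n`` chain fragments with propensity ``b (n-1) nu_n``
    at a uniformly chosen bond.  Populations are sampled onto ``t_grid``;
    per-run mass conservation is exact.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    nf = params.n_f
    a, b = params.a, params.b
    nu = np.zeros(nf, dtype=np.int64)
    nu[0] = params.N
    out = np.zeros((len(t_grid), nf))
    t = float(t_grid[0])
    gi = 0

    pairs = [(k, l) for k in range(1, nf + 1) for l in range(k, nf + 1) if k + l <= nf]
    while gi < len(t_grid):
        props = []
        for (k, l) in pairs:
            if k == l:
                props.append(a * nu[k - 1] * (nu[k - 1] - 1) / 2.0)
            else:
                props.append(a * nu[k - 1] * nu[l - 1])
        frag_off = len(props)
        for n in range(2, nf):
            props.append(b * (n - 1) * nu[n - 1])
        props = np.array(props)
        total = props.sum()
        if total <= 0.0:
            t = np.inf
        else:
            t += rng.exponential(1.0 / total)
        while gi < len(t_grid) and t_grid[gi] <= t:
            out[gi] = nu
            gi += 1
        if gi >= len(t_grid):
            break
        r = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(props), r))
        idx = min(idx, len(props) - 1)
        if idx < frag_off:
            k, l = pairs[idx]
            nu[k - 1] -= 1
            nu[l - 1] -= 1
            nu[k + l - 1] += 1
        else:
            n = idx - frag_off + 2
            m = int(rng.integers(1, n))  # bond position -> fragments (m, n-m)
            nu[n - 1] -= 1
            nu[m - 1] += 1
            nu[n - m - 1] += 1
    return METrajectory(t_grid=t_grid, nu=out, params=params)


# ---------------------------------------------------------------------------
# joint rate fitting (model / results)
# ---------------------------------------------------------------------------

@dataclass
class RingMEFitResults:
    """Fitted rates with uncertainties and residual diagnostics."""

    a: dict[str, float]          # association rate per dataset, ns^-1
    b: float                     # shared dissociation rate per bond, ns^-1
    params_log: np.ndarray       # solver parameters (log-space)
    bse_log: np.ndarray          # standard errors of the log-parameters
    cost: float                  # 0.5 * sum of squared residuals
    residuals: np.ndarray
    n_obs: int
    cost_path: list[float] = field(default_factory=list)
    dataset_names: list[str] = field(default_factory=list)

    @property
    def a_ratio(self) -> float:
        """Ratio of the first to the second dataset's association rate."""
        names = self.dataset_names
        return self.a[names[0]] / self.a[names[1]] if len(names) > 1 else np.nan

    def summary(self) -> str:
        lines = [
            "Ring-assembly master-equation fit",
            "=" * 48,
            f"{'parameter':<14}{'estimate':>14}{'rel. std. err.':>18}",
            "-" * 48,
        ]
        for i, name in enumerate(self.dataset_names):
            lines.append(
                f"{'a[' + name + ']':<14}{self.a[name]:>14.4e}"
                f"{self.bse_log[i]:>17.1%}"
            )
        lines.append(f"{'b':<14}{self.b:>14.4e}{self.bse_log[-1]:>17.1%}")
        lines.append("-" * 48)
        lines.append(f"observations: {self.n_obs}   cost: {self.cost:.4e}")
        if len(self.dataset_names) > 1:
            lines.append(f"a[{self.dataset_names[0]}] / a[{self.dataset_names[1]}]"
                         f" = {self.a_ratio:.3f}")
        return "\n".join(lines)


class RingAssemblyME:
    """Ring-assembly master-equation model for joint rate estimation.

    Built from one or more observed population tables ``nu_n(t)`` (e.g.
    the identical-hexamer and two-type-hexamer simulations); ``fit``
    estimates one association rate per dataset and a single dissociation
    rate ``b`` shared by all of them, by trust-region nonlinear least
    squares over log-parameters with multistart.
    """

    def __init__(
        self,
        datasets: dict[str, METrajectory],
        nu0s: dict[str, np.ndarray] | None = None,
        n_f: int = 6,
        N: int | None = None,
    ):
        if not datasets:
            raise MasterEquationError("need at least one dataset")
        self.names = list(datasets)
        self.datasets = datasets
        self.n_f = n_f
        self.nu0s = {}
        self.Ns = {}
        n = np.arange(1, n_f + 1)
        for name, tr in datasets.items():
            if tr.nu.shape[1] != n_f:
                raise MasterEquationError(f"dataset {name} has wrong width")
            if not np.any(tr.nu):
                raise MasterEquationError(f"dataset {name} is all zero")
            mass = tr.nu @ n
            if np.abs(mass - mass[0]).max() > 0.05 * mass[0]:
                raise MasterEquationError(f"dataset {name} does not conserve mass")
            nu0 = (
                nu0s[name]
                if nu0s is not None and name in nu0s
                else tr.nu[0].astype(float)
            )
            self.nu0s[name] = np.asarray(nu0, dtype=float)
            self.Ns[name] = int(round(float(self.nu0s[name] @ n)))

    def _residuals(self, log_params: np.ndarray) -> np.ndarray:
        a_vals = np.exp(log_params[:-1])
        b = float(np.exp(log_params[-1]))
        res = []
        for name, a in zip(self.names, a_vals):
            tr = self.datasets[name]
            params = MEParams(a=float(a), b=b, n_f=self.n_f, N=self.Ns[name])
            model = integrate_me(params, self.nu0s[name], tr.t_grid, rtol=1e-8)
            res.append((model.nu - tr.nu).ravel())
        return np.concatenate(res)

    def fit(self, multistart: int = 5) -> RingMEFitResults:
        # initial a from early-time monomer decay, b a log-spaced spread
        guesses = []
        a0 = []
        for name in self.names:
            tr = self.datasets[name]
            nu1 = tr.nu[:, 0]
            drop = np.nonzero(nu1 < 0.8 * nu1[0])[0]
            t_half = tr.t_grid[drop[0]] if len(drop) else tr.t_grid[-1]
            a0.append(max(1.0 / (max(nu1[0], 1.0) * max(t_half, 1e-12)), 1e-16))
        for b0 in np.geomspace(1e-7, 1e-2, multistart):
            guesses.append(np.log(np.array(a0 + [b0])))

        best = None
        cost_path = []
        for g in guesses:
            try:
                sol = least_squares(self._residuals, g, method="trf", xtol=1e-12)
            except MasterEquationError:
                continue
            cost_path.append(float(sol.cost))
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise MasterEquationError("all fit starts failed")

        # covariance of log-parameters from the Jacobian
        jac = best.jac
        dof = max(len(best.fun) - len(best.x), 1)
        sigma2 = 2.0 * best.cost / dof
        try:
            cov = sigma2 * np.linalg.inv(jac.T @ jac)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(len(best.x), np.nan)

        a_fit = {n: float(np.exp(v)) for n, v in zip(self.names, best.x[:-1])}
        return RingMEFitResults(
            a=a_fit,
            b=float(np.exp(best.x[-1])),
            params_log=best.x.copy(),
            bse_log=bse,
            cost=float(best.cost),
            residuals=best.fun.copy(),
            n_obs=len(best.fun),
            cost_path=sorted(cost_path, reverse=True),
            dataset_names=list(self.names),
        )


def fit_me(
    dataset_id: METrajectory,
    dataset_t3: METrajectory,
    nu0s: dict[str, np.ndarray] | None = None,
    n_f: int = 6,
) -> RingMEFitResults:
    """Joint fit of (a_id, a_T3, shared b) to two population tables."""
    model = RingAssemblyME(
        {"identical": dataset_id, "t3like": dataset_t3}, nu0s=nu0s, n_f=n_f
    )
    return model.fit()


# ---------------------------------------------------------------------------
# a <-> k_a conversion
# ---------------------------------------------------------------------------

def association_rate_conversion(a: float, c: float, N: int) -> float:
    """Molar association rate constant from the per-pair rate: with
    ``a = k_a c / N`` (c the species concentration in mol/L), returns
    ``k_a = a N / c`` converted from ns^-1 to s^-1 M^-1."""
    if c <= 0:
        raise MasterEquationError("concentration must be positive")
    if N < 1:
        raise MasterEquationError("N must be >= 1")
    return a * N / c * NS_PER_S


def association_rate_inverse(k_a_molar: float, c: float, N: int) -> float:
    """Per-pair rate a (ns^-1) from a molar rate constant (s^-1 M^-1)."""
    if c <= 0:
        raise MasterEquationError("concentration must be positive")
    return k_a_molar * c / N / NS_PER_S
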