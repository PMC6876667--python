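"""Covariance-structure modelling core.

Implements confirmatory factor analysis, MIMIC-style structural models and
multi-group models with full-information maximum likelihood (FIML) estimation
under ignorable missingness, plus the inferential utilities the analysis
pipeline needs: fit indices, nested model comparison, score-test modification
indices, Benjamini-Hochberg FDR, Tucker's congruence coefficient and a first
principal component.

Model representation
--------------------
Internally a model is held in RAM-like form over the stacked vector
``v = [observed endogenous y..., latents...]``::

    v = nu + A v + G x + zeta,   Cov(zeta) = S

where ``x`` are *fixed* exogenous regressors (covariates and, optionally,
complete exogenous predictors).  The implied conditional moments are

    mu(x) = F (I - A)^-1 (nu + G x),   Sigma = F (I - A)^-1 S (I - A)^-T F',

with ``F`` selecting the observed rows.  The casewise likelihood is the
multivariate normal density of each subject's observed sub-vector, grouped by
missingness pattern and evaluated from per-pattern cross-product matrices, so
an objective evaluation costs O(patterns * p^3) independent of sample size.

Conventions (recorded in ``FitResult.meta``):

* identification fixes every latent variance to 1 (all loadings free);
* the model chi-square is ``2 (l_saturated - l_model)`` where the saturated
  conditional model is estimated by EM;
* RMSEA uses the N divisor; saBIC uses the ``k * ln((N + 2) / 24)`` penalty;
* SRMR is the covariance-only variant computed against the saturated moments;
* the standardized solution is on the covariate-partialled correlation metric:
  variances exclude the contribution of designated covariates, so standardized
  loadings and paths are per SD of the covariate-adjusted variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "FitResult",
    "ComparisonResult",
    "ModificationIndex",
    "build_model",
    "implied_moments",
    "fiml_loglik",
    "fit_model",
    "fit_indices",
    "incremental_fit_indices",
    "modification_indices",
    "compare_nested",
    "bh_fdr",
    "congruence",
    "pca_first_component",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Entry:
    """One pattern-matrix cell: free (labelled) or fixed (valued)."""

    mat: str          # "A" | "S" | "G" | "nu"
    i: int
    j: int
    name: str         # canonical parameter name, e.g. "g=~vnr"
    free: bool
    value: float = 0.0
    start: float = 0.0


class ModelSpec:
    """Validated declarative SEM definition for one group.

    Build with :func:`build_model`; the constructor is internal.
    """

    def __init__(self, y_names, x_names, latent_names, covariates, entries,
                 definition=""):
        self.y_names = list(y_names)
        self.x_names = list(x_names)
        self.latent_names = list(latent_names)
        self.covariates = list(covariates)
        self.entries = list(entries)
        self.definition = definition
        self.ny = len(self.y_names)
        self.nl = len(self.latent_names)
        self.nx = len(self.x_names)
        self.nv = self.ny + self.nl
        self._validate()

    # -- helpers ----------------------------------------------------------
    def vindex(self, name: str) -> int:
        if name in self.y_names:
            return self.y_names.index(name)
        return self.ny + self.latent_names.index(name)

    @property
    def free_names(self):
        return [e.name for e in self.entries if e.free]

    @property
    def npar(self) -> int:
        return len(self.free_names)

    @property
    def n_moments(self) -> int:
        p, c = self.ny, self.nx
        return p * (p + 1) // 2 + p * (c + 1)

    @property
    def df(self) -> int:
        return self.n_moments - self.npar

    def _validate(self):
        names = [e.name for e in self.entries if e.free]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate free parameter labels: {dup}")
        for lat in self.latent_names:
            li = self.vindex(lat)
            has_ind = any(e.mat == "A" and e.j == li and e.i < self.ny
                          for e in self.entries)
            has_out = any(e.mat == "A" and e.j == li for e in self.entries)
            if not (has_ind or has_out):
                raise ValueError(f"latent '{lat}' has no indicators")
        # reject directed cycles through A
        adj = np.zeros((self.nv, self.nv), bool)
        for e in self.entries:
            if e.mat == "A":
                adj[e.i, e.j] = True
        reach = adj.copy()
        for _ in range(self.nv):
            reach = reach | (reach @ adj)
        if np.any(np.diag(reach)):
            raise ValueError("cyclic directed paths in model")

    def templates(self):
        """Numeric template matrices with fixed values filled in."""
        A = np.zeros((self.nv, self.nv))
        S = np.zeros((self.nv, self.nv))
        G = np.zeros((self.nv, self.nx))
        nu = np.zeros(self.nv)
        for e in self.entries:
            if e.free:
                continue
            _set(A, S, G, nu, e, e.value)
        return A, S, G, nu


def _set(A, S, G, nu, e: _Entry, value: float):
    if e.mat == "A":
        A[e.i, e.j] = value
    elif e.mat == "S":
        S[e.i, e.j] = value
        S[e.j, e.i] = value
    elif e.mat == "G":
        G[e.i, e.j] = value
    else:
        nu[e.i] = value


def _parse_term(term: str):
    """Parse 'x', '0.5*x' or 'label*x' -> (var, fixed_value, label)."""
    term = term.strip()
    if "*" in term:
        pre, var = term.split("*", 1)
        pre, var = pre.strip(), var.strip()
        try:
            return var, float(pre), None
        except ValueError:
            return var, None, pre
    return term, None, None


def build_model(definition: str, fixed_x=(), covariates=None,
                meanstructure: bool = True, variables=None) -> ModelSpec:
    """Build a :class:`ModelSpec` from a small lavaan-like text syntax.

    Supported lines (';' or newline separated, '#' comments)::

        g =~ matrix_reasoning + symbol_digit + vnr + tmtb_time   # loadings
        g ~ tbv + gm                                             # regressions
        matrix_reasoning ~~ vnr                                  # residual cov
        g ~~ 1*g                                                 # fix variance
        vnr ~ age + sex                                          # covariates

    Variables named in ``fixed_x`` are treated as fixed, complete exogenous
    regressors (conditional likelihood); everything else on a right-hand side
    is observed-endogenous or latent.  ``covariates`` (default: all of
    ``fixed_x``) marks which fixed regressors are nuisance covariates for the
    partialled standardization metric.

    Latent variances default to 1 (fixed) and latent means to 0 (fixed);
    observed intercepts, residual variances and all stated loadings/paths are
    free unless given a numeric prefix.
    """
    fixed_x = list(fixed_x)
    if covariates is None:
        covariates = list(fixed_x)
    lines = []
    for raw in definition.replace(";", "\n").splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            lines.append(line)

    latents, lhs_rel = [], []
    for line in lines:
        for op in ("=~", "~~", "~"):
            if op in line:
                lhs, rhs = line.split(op, 1)
                lhs_rel.append((lhs.strip(), op, rhs.strip()))
                if op == "=~" and lhs.strip() not in latents:
                    latents.append(lhs.strip())
                break
        else:
            raise ValueError(f"cannot parse model line: {line!r}")

    y_names = []

    def _note(var):
        if var in latents or var in fixed_x or var == "1":
            return
        if var not in y_names:
            y_names.append(var)

    for lhs, op, rhs in lhs_rel:
        _note(lhs)
        for term in rhs.split("+"):
            var, _, _ = _parse_term(term)
            _note(var)
    if variables is not None:
        unknown = [y for y in y_names if y not in variables]
        if unknown:
            raise ValueError(f"unknown variable(s): {unknown}")

    spec_kwargs = dict(y_names=y_names, x_names=fixed_x, latent_names=latents,
                       covariates=covariates, definition=definition)
    ny, nl = len(y_names), len(latents)
    nv = ny + nl

    def vidx(name):
        if name in y_names:
            return y_names.index(name)
        if name in latents:
            return ny + latents.index(name)
        raise ValueError(f"unknown variable: {name!r}")

    entries: list[_Entry] = []
    seen = set()

    def add(mat, i, j, name, free, value=0.0, start=0.0):
        key = (mat, i, j) if mat != "S" else ("S", min(i, j), max(i, j))
        if key in seen:
            # explicit line overrides an implicit default added later
            raise ValueError(f"parameter set twice: {name}")
        seen.add(key)
        entries.append(_Entry(mat, i, j, name, free, value, start))

    for lhs, op, rhs in lhs_rel:
        for term in rhs.split("+"):
            var, fixval, label = _parse_term(term)
            if op == "=~":
                i, j = vidx(var), vidx(lhs)
                name = label or f"{lhs}=~{var}"
                if fixval is None:
                    add("A", i, j, name, True, start=0.5)
                else:
                    add("A", i, j, name, False, value=fixval)
            elif op == "~~":
                i, j = vidx(lhs), vidx(var)
                name = label or _cov_name(lhs, var)
                if fixval is None:
                    start = 1.0 if i == j else 0.0
                    add("S", i, j, name, True, start=start)
                else:
                    add("S", i, j, name, False, value=fixval)
            else:  # regression "~"
                if var == "1":
                    i = vidx(lhs)
                    name = label or f"{lhs}~1"
                    if fixval is None:
                        add("nu", i, 0, name, True)
                    else:
                        add("nu", i, 0, name, False, value=fixval)
                    continue
                i = vidx(lhs)
                name = label or f"{lhs}~{var}"
                if var in fixed_x:
                    j = fixed_x.index(var)
                    if fixval is None:
                        add("G", i, j, name, True)
                    else:
                        add("G", i, j, name, False, value=fixval)
                else:
                    j = vidx(var)
                    if fixval is None:
                        add("A", i, j, name, True)
                    else:
                        add("A", i, j, name, False, value=fixval)

    # defaults: residual variances, latent variances/means, intercepts
    for k, yn in enumerate(y_names):
        key = ("S", k, k)
        if key not in seen:
            add("S", k, k, _cov_name(yn, yn), True, start=0.5)
        if meanstructure and ("nu", k, 0) not in seen:
            add("nu", k, 0, f"{yn}~1", True)
    for m, ln in enumerate(latents):
        k = ny + m
        if ("S", k, k) not in seen:
            add("S", k, k, _cov_name(ln, ln), False, value=1.0)
        # latent means fixed at 0 implicitly (template default)

    return ModelSpec(entries=entries, **spec_kwargs)


def _cov_name(a, b):
    return f"{a}~~{b}" if a <= b else f"{b}~~{a}"


# ---------------------------------------------------------------------------
# Prepared data: missingness patterns + cross-product sufficient statistics
# ---------------------------------------------------------------------------

class _GroupData:
    """One group's data, z-scaled, grouped by missingness pattern."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, y_means, y_sds,
                 x_means, x_sds, label):
        self.label = label
        self.n, self.ny = Y.shape
        self.nx = X.shape[1]
        self.y_means, self.y_sds = y_means, y_sds
        self.x_means, self.x_sds = x_means, x_sds
        obs = ~np.isnan(Y)
        codes = obs @ (1 << np.arange(self.ny, dtype=np.int64))
        self.patterns = []
        for code in np.unique(codes):
            rows = np.where(codes == code)[0]
            oidx = np.where(obs[rows[0]])[0]
            Yk = Y[np.ix_(rows, oidx)]
            Xk = X[rows]
            Z = np.hstack([Yk, Xk, np.ones((len(rows), 1))])
            self.patterns.append({
                "obs": oidx, "n": len(rows), "Y": Yk, "X": Xk,
                "M": Z.T @ Z,
            })
        # log-density Jacobian constant for reporting loglik on the raw scale
        self.log_jac = float(sum(
            p["n"] * np.log(y_sds[p["obs"]]).sum() for p in self.patterns))
        self.n_obs_cells = int(sum(p["n"] * len(p["obs"])
                                   for p in self.patterns))

    @property
    def n_patterns(self):
        return len(self.patterns)


def _prepare_data(model: ModelSpec, data: pd.DataFrame, group=None):
    """Split by group, z-scale with pooled statistics, build patterns."""
    missing = [c for c in model.y_names + model.x_names
               if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    Yall = data[model.y_names].to_numpy(float)
    Xall = data[model.x_names].to_numpy(float) if model.nx else \
        np.empty((len(data), 0))
    ok_x = ~np.isnan(Xall).any(axis=1) if model.nx else \
        np.ones(len(data), bool)
    any_y = ~np.isnan(Yall).all(axis=1)
    keep = ok_x & any_y
    n_dropped = int((~keep).sum())
    Yall, Xall = Yall[keep], Xall[keep]
    if len(Yall) == 0:
        raise ValueError("no usable rows (every row lacks data)")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        y_means = np.nanmean(Yall, axis=0)
        y_sds = np.nanstd(Yall, axis=0)
    if np.any(~np.isfinite(y_sds)) or np.any(y_sds <= 0):
        bad = [model.y_names[i] for i in range(model.ny)
               if not (np.isfinite(y_sds[i]) and y_sds[i] > 0)]
        raise ValueError(f"degenerate (constant or empty) variables: {bad}")
    x_means = Xall.mean(axis=0) if model.nx else np.empty(0)
    x_sds = Xall.std(axis=0) if model.nx else np.empty(0)
    x_sds = np.where(x_sds > 0, x_sds, 1.0)

    Ys = (Yall - y_means) / y_sds
    Xs = (Xall - x_means) / x_sds

    if group is None:
        glabels = [None]
        gmask = [np.ones(len(Ys), bool)]
    else:
        gcol = data.loc[keep, group]
        glabels = sorted(gcol.dropna().unique().tolist())
        if len(glabels) < 2:
            raise ValueError(f"grouping column {group!r} has <2 levels")
        gmask = [(gcol == g).to_numpy() for g in glabels]

    groups = [_GroupData(Ys[m], Xs[m], y_means, y_sds, x_means, x_sds, lab)
              for lab, m in zip(glabels, gmask)]
    # empirical covariate-partialled covariance of non-covariate fixed x,
    # used by the standardized solution (pooled across groups)
    pred_idx = [i for i, xn in enumerate(model.x_names)
                if xn not in model.covariates]
    cov_idx = [i for i, xn in enumerate(model.x_names)
               if xn in model.covariates]
    Sigma_pred = None
    if pred_idx:
        P = Xs[:, pred_idx]
        if cov_idx:
            C = np.hstack([Xs[:, cov_idx], np.ones((len(Xs), 1))])
            beta, *_ = np.linalg.lstsq(C, P, rcond=None)
            P = P - C @ beta
        Sigma_pred = (P.T @ P) / len(P)
    return groups, n_dropped, pred_idx, Sigma_pred


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _group_moments(A, S, G, nu, ny):
    nv = A.shape[0]
    IA = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
    Sigma_v = IA @ S @ IA.T
    Sigma = Sigma_v[:ny, :ny]
    Gt = (IA @ G)[:ny] if G.shape[1] else np.empty((ny, 0))
    a = (IA @ nu)[:ny]
    return Sigma, Gt, a, IA, Sigma_v


def _pattern_loglik(Sigma, Gt, a, gd: _GroupData, penalized=False):
    """Sum of casewise log-densities from pattern cross-products.

    With ``penalized`` a non-positive-definite pattern submatrix yields a
    large negative value scaled by the violation, so line searches retain a
    slope back toward the feasible region instead of hitting a flat cliff.
    """
    total = 0.0
    for p in gd.patterns:
        o = p["obs"]
        Sk = Sigma[np.ix_(o, o)]
        try:
            L = np.linalg.cholesky(Sk)
        except np.linalg.LinAlgError:
            if not penalized:
                return -np.inf
            w = np.linalg.eigvalsh(Sk)
            viol = float(np.clip(-w, 0.0, None).sum())
            return -1e7 * (1.0 + viol)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        pk = len(o)
        W = np.hstack([np.eye(pk), -Gt[o], -a[o, None]])
        R = W @ p["M"] @ W.T
        Sinv_R = np.linalg.solve(L.T, np.linalg.solve(L, R))
        total += -0.5 * (p["n"] * (pk * _LOG2PI + logdet) + np.trace(Sinv_R))
    return total


class _Objective:
    """Maps a theta vector to per-group matrices and the FIML loglik."""

    def __init__(self, model: ModelSpec, groups, equal=(), extra_free=()):
        self.model = model
        self.groups = groups
        self.multi = len(groups) > 1 and groups[0].label is not None
        shared = _shared_predicate(equal)
        # per-group entry lists (template entries + requested extra frees)
        self.group_entries = []
        names = []
        for g, gd in enumerate(groups):
            ents = list(model.entries) + [
                _Entry(*ef[:3], name=ef[3], free=True, start=ef[4])
                for ef in extra_free if ef[5] in (None, gd.label)]
            self.group_entries.append(ents)
            for e in ents:
                if not e.free:
                    continue
                nm = e.name if (not self.multi or shared(e)) \
                    else f"{e.name}|{gd.label}"
                names.append(nm)
        self.theta_names = list(dict.fromkeys(names))
        self.index = {nm: k for k, nm in enumerate(self.theta_names)}
        # resolve each free entry to a theta slot
        self.slots = []
        for g, gd in enumerate(groups):
            slot = []
            for e in self.group_entries[g]:
                if e.free:
                    nm = e.name if (not self.multi or shared(e)) \
                        else f"{e.name}|{gd.label}"
                    slot.append((e, self.index[nm]))
            self.slots.append(slot)
        self.templates = [model.templates() for _ in groups]
        self.n_total = sum(gd.n for gd in groups)
        self.log_jac = sum(gd.log_jac for gd in groups)

    @property
    def npar(self):
        return len(self.theta_names)

    def start(self):
        th = np.zeros(self.npar)
        for g in range(len(self.groups)):
            for e, k in self.slots[g]:
                th[k] = e.start
        return th

    def matrices(self, theta, g):
        A0, S0, G0, nu0 = self.templates[g]
        A, S, G, nu = A0.copy(), S0.copy(), G0.copy(), nu0.copy()
        for e, k in self.slots[g]:
            _set(A, S, G, nu, e, theta[k])
        return A, S, G, nu

    def loglik(self, theta, penalized=False):
        """FIML loglik of the scaled data (no Jacobian constant)."""
        total = 0.0
        for g, gd in enumerate(self.groups):
            A, S, G, nu = self.matrices(theta, g)
            try:
                Sigma, Gt, a, _, _ = _group_moments(A, S, G, nu, self.model.ny)
            except np.linalg.LinAlgError:
                return -1e9 if penalized else -np.inf
            lk = _pattern_loglik(Sigma, Gt, a, gd, penalized=penalized)
            if not np.isfinite(lk):
                return -np.inf
            total += lk
        return total

    def objective(self, theta):
        lk = self.loglik(theta, penalized=True)
        return -lk / self.n_total


def _shared_predicate(equal):
    """Map 'equal' categories/names to a predicate over entries."""
    equal = set(equal)

    def shared(e: _Entry):
        if e.name in equal:
            return True
        if e.mat == "A" and "=~" in e.name and "loadings" in equal:
            return True
        if e.mat == "nu" and e.name.endswith("~1") and "intercepts" in equal:
            return True
        if e.mat == "S" and e.i == e.j and "residuals" in equal:
            return True
        if e.mat == "S" and e.i != e.j and "residual_covariances" in equal:
            return True
        if e.mat == "A" and "=~" not in e.name and "regressions" in equal:
            return True
        if e.mat == "G" and "covariate_slopes" in equal:
            return True
        return False

    return shared


# ---------------------------------------------------------------------------
# Saturated and baseline conditional models
# ---------------------------------------------------------------------------

def _saturated_loglik(gd: _GroupData, tol=1e-10, max_iter=2000):
    """EM for the unrestricted conditional MVN model y | x ~ N(G x + a, S).

    Returns the maximized loglik of the scaled data.  With a single complete
    pattern the closed form is used.
    """
    p, c, n = gd.ny, gd.nx, gd.n
    if gd.n_patterns == 1 and len(gd.patterns[0]["obs"]) == p:
        pat = gd.patterns[0]
        M = pat["M"]
        Myw, Mww = M[:p, p:], M[p:, p:]
        Gam = np.linalg.solve(Mww, Myw.T).T
        R = M[:p, :p] - Gam @ Myw.T
        Sigma = (R + R.T) / (2 * n)
        Gt, a = Gam[:, :c], Gam[:, c]
        return _pattern_loglik(Sigma, Gt, a, gd), Sigma, Gt, a

    # initialize from available-case univariate regressions
    Gam = np.zeros((p, c + 1))
    resid_var = np.ones(p)
    for j in range(p):
        rows_y, rows_w = [], []
        for pat in gd.patterns:
            o = list(pat["obs"])
            if j in o:
                rows_y.append(pat["Y"][:, o.index(j)])
                rows_w.append(np.hstack([pat["X"],
                                         np.ones((pat["n"], 1))]))
        yj = np.concatenate(rows_y)
        Wj = np.vstack(rows_w)
        bj, *_ = np.linalg.lstsq(Wj, yj, rcond=None)
        Gam[j] = bj
        r = yj - Wj @ bj
        resid_var[j] = max(float(r @ r / len(r)), 1e-6)
    Sigma = np.diag(resid_var)

    Wfull = [np.hstack([pat["X"], np.ones((pat["n"], 1))])
             for pat in gd.patterns]
    last = -np.inf
    for _ in range(max_iter):
        Tyy = np.zeros((p, p))
        Tyw = np.zeros((p, c + 1))
        Tww = np.zeros((c + 1, c + 1))
        for pat, W in zip(gd.patterns, Wfull):
            o = pat["obs"]
            m = np.setdiff1d(np.arange(p), o)
            mu = W @ Gam.T                       # n_k x p
            Yfull = np.empty((pat["n"], p))
            Yfull[:, o] = pat["Y"]
            Vmm = np.zeros((len(m), len(m)))
            if len(m):
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                B = np.linalg.solve(Soo, Smo.T).T
                Yfull[:, m] = mu[:, m] + (pat["Y"] - mu[:, o]) @ B.T
                Vmm = Sigma[np.ix_(m, m)] - B @ Smo.T
            Tyy += Yfull.T @ Yfull
            if len(m):
                Tyy[np.ix_(m, m)] += pat["n"] * Vmm
            Tyw += Yfull.T @ W
            Tww += W.T @ W
        Gam = np.linalg.solve(Tww, Tyw.T).T
        Sg = (Tyy - Gam @ Tyw.T - Tyw @ Gam.T + Gam @ Tww @ Gam.T) / n
        Sigma = (Sg + Sg.T) / 2
        lk = _pattern_loglik(Sigma, Gam[:, :c], Gam[:, c], gd)
        if lk - last < tol * (1.0 + abs(lk)):
            last = lk
            break
        last = lk
    return last, Sigma, Gam[:, :c], Gam[:, c]


def _baseline_loglik(gd: _GroupData):
    """Independence baseline: diagonal Sigma, covariate slopes retained.

    Factorizes into per-variable univariate ML regressions on the observed
    rows, so it has a closed form even with missing data.
    """
    p, c = gd.ny, gd.nx
    total = 0.0
    for j in range(p):
        ys, Ws = [], []
        for pat in gd.patterns:
            o = list(pat["obs"])
            if j in o:
                ys.append(pat["Y"][:, o.index(j)])
                Ws.append(np.hstack([pat["X"], np.ones((pat["n"], 1))]))
        yj = np.concatenate(ys)
        Wj = np.vstack(Ws)
        bj, *_ = np.linalg.lstsq(Wj, yj, rcond=None)
        r = yj - Wj @ bj
        s2 = max(float(r @ r / len(r)), 1e-12)
        total += -0.5 * len(r) * (_LOG2PI + math.log(s2) + 1.0)
    return total


def _baseline_npar(model: ModelSpec):
    return model.ny * (model.nx + 2)          # slopes + intercept + variance


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates, standardized solution, inference and fit of one model."""

    model: ModelSpec
    params: pd.DataFrame
    loglik: float
    npar: int
    n: int
    n_groups: int
    n_patterns: int
    group_labels: list
    chisq: float | None = None
    df: int | None = None
    pvalue: float | None = None
    baseline_chisq: float | None = None
    baseline_df: int | None = None
    cfi: float | None = None
    tli: float | None = None
    rmsea: float | None = None
    srmr: float | None = None
    aic: float = np.nan
    sabic: float = np.nan
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = np.nan
    warnings: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    _internal: dict = field(default_factory=dict, repr=False)

    # -- access helpers ---------------------------------------------------
    def param(self, name: str, group=None) -> pd.Series:
        t = self.params
        rows = t[t["name"] == name]
        if group is not None:
            rows = rows[rows["group"] == group]
        if len(rows) == 0:
            raise KeyError(f"no parameter {name!r} (group={group!r})")
        return rows.iloc[0]

    def loadings(self, latent: str, group=None) -> pd.Series:
        t = self.params
        sel = t["name"].str.startswith(f"{latent}=~")
        rows = t[sel]
        if group is not None:
            rows = rows[rows["group"] == group]
        out = rows.set_index(rows["name"].str.replace(f"{latent}=~", "",
                                                      regex=False))
        return out["std"]

    def r_squared(self, variable: str) -> dict:
        """Proportion of a variable's (covariate-partialled) model-implied
        variance explained by its predictors, per group."""
        obj = self._internal["objective"]
        theta = self._internal["theta"]
        pred_idx = self._internal.get("pred_idx", [])
        Sigma_pred = self._internal.get("Sigma_pred")
        i = self.model.vindex(variable)
        out = {}
        for g, gd in enumerate(obj.groups):
            A, S, G, nu = obj.matrices(theta, g)
            S_tot = S.copy()
            if pred_idx and Sigma_pred is not None:
                Gp = G[:, pred_idx]
                S_tot = S_tot + Gp @ Sigma_pred @ Gp.T
            nv = self.model.nv
            IA = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
            Sigma_v = IA @ S_tot @ IA.T
            out[gd.label] = 1.0 - S[i, i] / Sigma_v[i, i]
        return out if self.n_groups > 1 else {None: out[None]}

    def meets(self, cfi=0.95, tli=0.95, rmsea=0.05, srmr=0.05) -> bool:
        """Preregistered-style fit check: CFI,TLI > a and RMSEA,SRMR < b."""
        if self.df == 0:
            return True
        return (self.cfi > cfi and self.tli > tli
                and self.rmsea < rmsea and self.srmr < srmr)

    def to_tsv(self, path):
        self.params.to_csv(path, sep="\t", index=False)

    def indices_dict(self):
        return {k: getattr(self, k) for k in
                ("chisq", "df", "pvalue", "cfi", "tli", "rmsea", "srmr",
                 "aic", "sabic", "loglik", "npar", "n", "converged")}


@dataclass
class ComparisonResult:
    """Nested model comparison by chi-square difference, AIC and saBIC."""

    delta_chisq: float
    delta_df: int
    pvalue: float
    delta_aic: float
    delta_sabic: float

    @property
    def prefers(self):
        """Per-criterion preference for the constrained model."""
        return {
            "chisq": self.pvalue > 0.05,
            "aic": self.delta_aic <= 0,
            "sabic": self.delta_sabic <= 0,
        }


@dataclass
class ModificationIndex:
    parameter: str
    mi: float
    epc: float
    group: object = None


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_model(model: ModelSpec, data: pd.DataFrame, group=None, equal=(),
              free_latent_variance=None, free_latent_mean=None,
              compute_fit: bool = True, compute_se: bool = True,
              bounded: bool = False, max_iter: int = 1000) -> FitResult:
    """Fit a model by FIML and return the full :class:`FitResult`.

    Parameters
    ----------
    group : str, optional
        Column defining a multi-group fit.
    equal : sequence
        Parameter categories or explicit names constrained equal across
        groups ("loadings", "intercepts", "residuals",
        "residual_covariances", "regressions", "covariate_slopes").
    free_latent_variance, free_latent_mean : bool, optional
        Free the latent variance / mean in every group after the first.
        Defaults: variance freed when loadings are constrained, mean freed
        when intercepts are constrained (standard invariance conventions).
    """
    groups, n_dropped, pred_idx, Sigma_pred = _prepare_data(model, data, group)
    multi = group is not None
    if free_latent_variance is None:
        free_latent_variance = multi and "loadings" in set(equal)
    if free_latent_mean is None:
        free_latent_mean = multi and "intercepts" in set(equal)

    extra = []
    if multi:
        for gd in groups[1:]:
            for m, lat in enumerate(model.latent_names):
                k = model.ny + m
                if free_latent_variance:
                    extra.append(("S", k, k, f"var({lat})", 1.0, gd.label))
                if free_latent_mean:
                    extra.append(("nu", k, 0, f"mean({lat})", 0.0, gd.label))

    obj = _Objective(model, groups, equal=equal, extra_free=extra)
    th0 = obj.start()
    bounds = None
    if bounded:
        # variance parameters kept weakly positive (scaled metric)
        bounds = [(None, None)] * obj.npar
        for g in range(len(groups)):
            for e, k in obj.slots[g]:
                if e.mat == "S" and e.i == e.j:
                    bounds[k] = (1e-4, None)
    opts = {"maxiter": max_iter, "maxfun": 10 ** 6,
            "ftol": 1e-12, "gtol": 1e-7}
    res = optimize.minimize(obj.objective, th0, method="L-BFGS-B",
                            jac="3-point", bounds=bounds, options=opts)
    for _ in range(2):
        # an abnormal line-search exit leaves a usable point; restarting
        # there resets the Hessian memory and usually completes the fit
        if res.success or (res.jac is not None
                           and np.max(np.abs(res.jac)) < 1e-4):
            break
        res2 = optimize.minimize(obj.objective, res.x, method="L-BFGS-B",
                                 jac="3-point", bounds=bounds, options=opts)
        if res2.fun > res.fun:
            break
        res = res2

    def _degenerate(th):
        for g in range(len(groups)):
            _, S, _, _ = obj.matrices(th, g)
            if np.any(np.diag(S)[:model.ny] < 1e-3):
                return True
        return False

    if _degenerate(res.x):
        # likelihood ridges (e.g. null populations) admit single-indicator
        # Heywood solutions tied with the regular one; tie-break by
        # restarting from near-zero loadings and preferring the
        # non-degenerate optimum when it is not materially worse
        th_alt = th0.copy()
        for g in range(len(groups)):
            for e, k in obj.slots[g]:
                if e.mat == "A" and "=~" in e.name:
                    th_alt[k] = 0.01
        res2 = optimize.minimize(obj.objective, th_alt, method="L-BFGS-B",
                                 jac="3-point", bounds=bounds, options=opts)
        # "not materially worse" = within ~one parameter's worth of chance
        # likelihood improvement (2 loglik units)
        if res2.fun <= res.fun + 2.0 / obj.n_total and \
                not _degenerate(res2.x):
            res = res2
    theta = res.x
    fitwarn = []
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None \
        else np.nan
    converged = bool(res.success) or grad_norm < 1e-4
    if not converged:
        fitwarn.append(f"non-convergence: {res.message} "
                       f"(|grad|max={grad_norm:.2e}, nit={res.nit})")

    lk = obj.loglik(theta)
    loglik_raw = lk - obj.log_jac
    n_total = obj.n_total
    k_free = obj.npar
    aic = -2.0 * loglik_raw + 2.0 * k_free
    sabic = -2.0 * loglik_raw + k_free * math.log((n_total + 2.0) / 24.0)

    # Heywood screening
    for g, gd in enumerate(groups):
        _, S, _, _ = obj.matrices(theta, g)
        if np.any(np.diag(S)[:model.ny] < 0):
            fitwarn.append("heywood: negative residual variance")
            break

    # ---- chi-square and fit indices ------------------------------------
    chisq = df = pvalue = cfi = tli = rmsea = srmr = None
    base_chi = base_df = None
    if compute_fit:
        l_sat, sat_parts = 0.0, []
        l_base = 0.0
        for gd in groups:
            ls, Ssat, _, _ = _saturated_loglik(gd)
            l_sat += ls
            sat_parts.append(Ssat)
            l_base += _baseline_loglik(gd)
        df = model.n_moments * len(groups) - k_free
        chisq = max(2.0 * (l_sat - lk), 0.0)
        pvalue = float(stats.chi2.sf(chisq, df)) if df > 0 else 1.0
        base_df = (model.n_moments - _baseline_npar(model)) * len(groups)
        base_chi = max(2.0 * (l_sat - l_base), 0.0)
        cfi, tli, rmsea = incremental_fit_indices(
            chisq, df, base_chi, base_df, n_total)
        # SRMR: covariance-only residuals vs the saturated moments
        sq_sum, n_mom = 0.0, 0
        for g, gd in enumerate(groups):
            A, S, G, nu = obj.matrices(theta, g)
            Sigma, _, _, _, _ = _group_moments(A, S, G, nu, model.ny)
            Ssat = sat_parts[g]
            d_obs = np.sqrt(np.diag(Ssat))
            d_imp = np.sqrt(np.clip(np.diag(Sigma), 1e-12, None))
            Robs = Ssat / np.outer(d_obs, d_obs)
            Rimp = Sigma / np.outer(d_imp, d_imp)
            iu = np.triu_indices(model.ny, 1)
            sq_sum += np.sum((Robs[iu] - Rimp[iu]) ** 2)
            sq_sum += np.sum((1.0 - np.diag(Sigma) / np.diag(Ssat)) ** 2)
            n_mom += model.ny * (model.ny + 1) // 2
        srmr = math.sqrt(sq_sum / n_mom)
        if df == 0:
            rmsea, cfi, tli = 0.0, 1.0, 1.0

    # ---- covariance of theta (observed information) ---------------------
    theta_cov = None
    if compute_se:
        H = _num_hessian(lambda t: -obj.loglik(t), theta)
        try:
            theta_cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            theta_cov = np.linalg.pinv(H)
            fitwarn.append("singular information matrix; pseudo-inverse SEs")
        if np.any(np.diag(theta_cov) < 0):
            fitwarn.append("negative variance in information inverse")

    params = _param_table(obj, theta, theta_cov, pred_idx, Sigma_pred)

    meta = {
        "identification": "latent variances fixed to 1",
        "rmsea_divisor": "N",
        "sabic_penalty": "k*ln((N+2)/24)",
        "srmr": "covariance-only, vs saturated moments",
        "standardization": "covariate-partialled metric",
        "estimator": "FIML (conditional on fixed x)",
        "n_rows_dropped": n_dropped,
    }
    internal = {"objective": obj, "theta": theta, "theta_cov": theta_cov,
                "data_columns": tuple(model.y_names),
                "equal": tuple(equal), "pred_idx": pred_idx,
                "Sigma_pred": Sigma_pred}
    return FitResult(
        model=model, params=params, loglik=loglik_raw, npar=k_free,
        n=n_total, n_groups=len(groups),
        n_patterns=sum(gd.n_patterns for gd in groups),
        group_labels=[gd.label for gd in groups],
        chisq=chisq, df=df, pvalue=pvalue,
        baseline_chisq=base_chi, baseline_df=base_df,
        cfi=cfi, tli=tli, rmsea=rmsea, srmr=srmr,
        aic=aic, sabic=sabic, converged=converged, n_iter=res.nit,
        grad_norm=grad_norm, warnings=fitwarn, meta=meta,
        _internal=internal)


def _raw_std_vectors(obj: _Objective, theta, pred_idx, Sigma_pred):
    """Raw-metric and standardized parameter values for every free entry."""
    model = obj.model
    raw, std = [], []
    for g, gd in enumerate(obj.groups):
        A, S, G, nu = obj.matrices(theta, g)
        ny = model.ny
        nv = model.nv
        IA = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
        S_tot = S.copy()
        if pred_idx and Sigma_pred is not None:
            Gp = G[:, pred_idx]
            S_tot = S_tot + Gp @ Sigma_pred @ Gp.T
        Sigma_v = IA @ S_tot @ IA.T
        sd_v = np.sqrt(np.clip(np.diag(Sigma_v), 1e-12, None))
        # scale vector back to raw units
        d = np.concatenate([gd.y_sds, np.ones(model.nl)])
        for e, k in obj.slots[g]:
            v = theta[k]
            if e.mat == "A":
                raw.append(v * d[e.i] / d[e.j])
                std.append(v * sd_v[e.j] / sd_v[e.i])
            elif e.mat == "S":
                raw.append(v * d[e.i] * d[e.j])
                denom = math.sqrt(max(S[e.i, e.i] * S[e.j, e.j], 1e-24))
                std.append(v / denom if e.i != e.j
                           else v / max(Sigma_v[e.i, e.i], 1e-12))
            elif e.mat == "G":
                xn = model.x_names[e.j]
                raw.append(v * d[e.i] / gd.x_sds[e.j])
                if xn in model.covariates:
                    std.append(v / sd_v[e.i])
                else:
                    sd_x = math.sqrt(Sigma_pred[pred_idx.index(e.j),
                                                pred_idx.index(e.j)]) \
                        if Sigma_pred is not None else 1.0
                    std.append(v * sd_x / sd_v[e.i])
            else:  # intercept / latent mean
                if e.i < ny:
                    raw.append(gd.y_means[e.i] + gd.y_sds[e.i] * v)
                else:
                    raw.append(v)
                std.append(v / sd_v[e.i])
    return np.array(raw), np.array(std)


def _param_table(obj: _Objective, theta, theta_cov, pred_idx, Sigma_pred):
    model = obj.model
    raw, std = _raw_std_vectors(obj, theta, pred_idx, Sigma_pred)
    names, grps, thidx = [], [], []
    for g, gd in enumerate(obj.groups):
        for e, k in obj.slots[g]:
            names.append(e.name)
            grps.append(gd.label)
            thidx.append(k)
    se = np.full(len(raw), np.nan)
    std_se = np.full(len(raw), np.nan)
    if theta_cov is not None:
        Jr = _num_jacobian(
            lambda t: _raw_std_vectors(obj, t, pred_idx, Sigma_pred)[0],
            theta)
        Js = _num_jacobian(
            lambda t: _raw_std_vectors(obj, t, pred_idx, Sigma_pred)[1],
            theta)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.einsum("ij,jk,ik->i", Jr, theta_cov, Jr))
            std_se = np.sqrt(np.einsum("ij,jk,ik->i", Js, theta_cov, Js))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = std / std_se
        p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "name": names, "group": grps, "est": raw, "se": se,
        "std": std, "std_se": std_se, "z": z, "p": p,
        "theta_index": thidx,
    })


def _num_hessian(f, x, rel_step=1e-5):
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        fp[i] = f(x + ei)
        fm[i] = f(x - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    return H


def _num_jacobian(f, x, rel_step=1e-6):
    f0 = np.asarray(f(x), float)
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy(); xp[i] += h
        xm = x.copy(); xm[i] -= h
        J[:, i] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# Public single-shot operations
# ---------------------------------------------------------------------------

def implied_moments(model: ModelSpec, theta):
    """Model-implied covariance and mean of the observed variables.

    ``theta`` maps free-parameter names to values (dict) or is a vector in
    ``model.free_names`` order.  For models with fixed-x regressors the mean
    is returned at x = 0.
    """
    if not isinstance(theta, dict):
        theta = dict(zip(model.free_names, np.asarray(theta, float)))
    missing = [n for n in model.free_names if n not in theta]
    if missing:
        raise ValueError(f"missing parameter values: {missing}")
    A0, S0, G0, nu0 = model.templates()
    for e in model.entries:
        if e.free:
            _set(A0, S0, G0, nu0, e, theta[e.name])
    Sigma, Gt, a, _, _ = _group_moments(A0, S0, G0, nu0, model.ny)
    return Sigma, a


def fiml_loglik(model: ModelSpec, theta, data: pd.DataFrame) -> float:
    """Casewise (FIML) log-likelihood of ``data`` at ``theta`` (raw scale).

    Each subject contributes the log-density of their observed sub-vector
    under the implied multivariate normal; subjects with no observed
    modelled variable are rejected.
    """
    Y = data[model.y_names].to_numpy(float)
    if np.isnan(Y).all(axis=1).any():
        raise ValueError("subjects with no observed modelled variable")
    if not isinstance(theta, dict):
        theta = dict(zip(model.free_names, np.asarray(theta, float)))
    A0, S0, G0, nu0 = model.templates()
    for e in model.entries:
        if e.free:
            _set(A0, S0, G0, nu0, e, theta[e.name])
    Sigma, Gt, a, _, _ = _group_moments(A0, S0, G0, nu0, model.ny)
    X = data[model.x_names].to_numpy(float) if model.nx else \
        np.empty((len(data), 0))
    total = 0.0
    for i in range(len(Y)):
        o = np.where(~np.isnan(Y[i]))[0]
        So = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"non-positive-definite submatrix for pattern {tuple(o)}")
        r = Y[i, o] - a[o] - Gt[o] @ X[i]
        total += -0.5 * (len(o) * _LOG2PI + logdet
                         + float(r @ np.linalg.solve(So, r)))
    return total


def incremental_fit_indices(chisq_m, df_m, chisq_b, df_b, n):
    """CFI, TLI and RMSEA from model and baseline chi-squares (N divisor)."""
    num = max(chisq_m - df_m, 0.0)
    den = max(chisq_b - df_b, chisq_m - df_m, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df_m > 0 and df_b > 0 and (chisq_b / df_b) != 1.0:
        tli = ((chisq_b / df_b) - (chisq_m / df_m)) / ((chisq_b / df_b) - 1.0)
    else:
        tli = 1.0
    rmsea = math.sqrt(max(chisq_m - df_m, 0.0) / (df_m * n)) if df_m > 0 \
        else 0.0
    return cfi, tli, rmsea


def fit_indices(fit: FitResult, baseline: FitResult | None = None):
    """Recompute CFI/TLI/RMSEA (and echo SRMR/AIC/saBIC) for a fitted model.

    ``baseline`` defaults to the independence model evaluated during the fit.
    """
    if baseline is not None:
        bchi, bdf = baseline.chisq, baseline.df
    else:
        bchi, bdf = fit.baseline_chisq, fit.baseline_df
    cfi, tli, rmsea = incremental_fit_indices(fit.chisq, fit.df, bchi, bdf,
                                              fit.n)
    if fit.df == 0:
        cfi, tli, rmsea = 1.0, 1.0, 0.0
    return {"chisq": fit.chisq, "df": fit.df, "cfi": cfi, "tli": tli,
            "rmsea": rmsea, "srmr": fit.srmr, "aic": fit.aic,
            "sabic": fit.sabic}


def _moment_derivatives(obj: _Objective, theta, g):
    """Central-difference derivatives of (Sigma, Gt, a) wrt each free
    parameter, for one group."""
    model = obj.model

    def mom(th):
        A, S, G, nu = obj.matrices(th, g)
        Sigma, Gt, a, _, _ = _group_moments(A, S, G, nu, model.ny)
        return Sigma, Gt, a

    out = []
    for k in range(len(theta)):
        h = 1e-5 * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += h
        tm = theta.copy(); tm[k] -= h
        Sp, Gp, ap = mom(tp)
        Sm, Gm, am = mom(tm)
        out.append(((Sp - Sm) / (2 * h), (Gp - Gm) / (2 * h),
                    (ap - am) / (2 * h)))
    return out


def _expected_information(obj: _Objective, theta, extra_derivs=None):
    """Normal-theory expected (Fisher) information of the FIML model at
    ``theta``, pattern-weighted; ``extra_derivs`` appends candidate
    directions given as per-group (dSigma, dGt, da) triples."""
    model = obj.model
    k = len(theta)
    m = k + (len(extra_derivs[0]) if extra_derivs else 0)
    info = np.zeros((m, m))
    for g, gd in enumerate(obj.groups):
        A, S, G, nu = obj.matrices(theta, g)
        Sigma, Gt, a, _, _ = _group_moments(A, S, G, nu, model.ny)
        derivs = _moment_derivatives(obj, theta, g)
        if extra_derivs:
            derivs = derivs + list(extra_derivs[g])
        for pat in gd.patterns:
            o = pat["obs"]
            nk = pat["n"]
            pk = len(o)
            Sk = Sigma[np.ix_(o, o)]
            Skinv = np.linalg.inv(Sk)
            nx = gd.nx
            Mxx = pat["M"][pk:, pk:]          # [X 1]' [X 1] cross-products
            As, Us = [], []
            for dS, dG, da in derivs:
                As.append(Skinv @ dS[np.ix_(o, o)])
                # per-subject mean derivative stacked as [dGt | da]
                Us.append(np.hstack([dG[o], da[o, None]]))
            for i in range(m):
                for j in range(i, m):
                    cov_part = 0.5 * nk * np.sum(As[i] * As[j].T)
                    # mean part: sum over subjects of u_i' Sk^-1 u_j with
                    # u = dGt x + da, via the [X 1] cross-product matrix
                    mean_part = np.trace(Us[i].T @ Skinv @ Us[j] @ Mxx)
                    info[i, j] += cov_part + mean_part
                    if i != j:
                        info[j, i] = info[i, j]
    return info


def modification_indices(fit: FitResult, candidates=None):
    """Score-test (Lagrange multiplier) modification indices for fixed
    residual covariances.

    For each candidate (default: every pair of modelled endogenous variables
    whose residual covariance is fixed at zero) the expected 1-df chi-square
    drop and the expected parameter change are computed from the observed
    score and the normal-theory expected information at the restricted
    optimum.  Sorted descending.
    """
    obj: _Objective = fit._internal["objective"]
    theta = fit._internal["theta"]
    model = fit.model

    present = {("S", min(e.i, e.j), max(e.i, e.j))
               for ents in obj.group_entries for e in ents if e.mat == "S"}
    if candidates is None:
        candidates = []
        for i in range(model.ny):
            for j in range(i + 1, model.ny):
                if ("S", i, j) not in present:
                    candidates.append((model.y_names[i], model.y_names[j]))

    out = []
    todo = []
    for (va, vb) in candidates:
        i, j = model.vindex(va), model.vindex(vb)
        if ("S", min(i, j), max(i, j)) in present:
            out.append(ModificationIndex(_cov_name(va, vb), 0.0, 0.0))
        else:
            todo.append((va, vb, i, j))
    if not todo:
        out.sort(key=lambda mi: -mi.mi)
        return out

    # candidate moment derivatives: dSigma = e_ij + e_ji propagated
    extra = []
    for g in range(len(obj.groups)):
        A, S, G, nu = obj.matrices(theta, g)
        nv = model.nv
        IA = np.linalg.solve(np.eye(nv) - A, np.eye(nv))
        F = IA[:model.ny]
        triples = []
        for (_, _, i, j) in todo:
            dSv = np.outer(F[:, i], F[:, j])
            dS = dSv + dSv.T
            triples.append((dS, np.zeros_like(G[:model.ny]),
                            np.zeros(model.ny)))
        extra.append(triples)

    info = _expected_information(obj, theta, extra_derivs=extra)
    k = len(theta)
    Ithth = info[:k, :k]

    # observed scores for the candidates
    def nll_t(tval, i, j):
        total = 0.0
        for g, gd in enumerate(obj.groups):
            A, S, G, nu = obj.matrices(theta, g)
            S[i, j] = S[j, i] = tval
            try:
                Sg, Gt, a, _, _ = _group_moments(A, S, G, nu, model.ny)
            except np.linalg.LinAlgError:
                return np.inf
            lk = _pattern_loglik(Sg, Gt, a, gd)
            if not np.isfinite(lk):
                return np.inf
            total += lk
        return -total

    h = 1e-6
    for idx, (va, vb, i, j) in enumerate(todo):
        s = -(nll_t(h, i, j) - nll_t(-h, i, j)) / (2 * h)
        row = info[k + idx]
        Itt = row[k + idx]
        It_th = row[:k]
        try:
            v = Itt - It_th @ np.linalg.solve(Ithth, It_th)
        except np.linalg.LinAlgError:
            v = Itt
        if v <= max(1e-12 * max(Itt, 1.0), 0.0):
            warnings.warn(f"non-positive information for candidate "
                          f"{va}~~{vb}; skipped")
            continue
        out.append(ModificationIndex(_cov_name(va, vb),
                                     float(s * s / v), float(s / v)))
    out.sort(key=lambda mi: -mi.mi)
    return out


def _unit(n, i, h):
    e = np.zeros(n)
    e[i] = h
    return e


def compare_nested(free: FitResult, constrained: FitResult) -> ComparisonResult:
    """Chi-square difference test plus AIC / saBIC differences
    (constrained minus free)."""
    if free.n != constrained.n or \
            free._internal.get("data_columns") != \
            constrained._internal.get("data_columns"):
        raise ValueError("models were not fitted to the same data")
    ddf = constrained.df - free.df if free.df is not None else \
        free.npar - constrained.npar
    if ddf < 0:
        raise ValueError("'constrained' model has more free parameters than "
                         "'free'; not a nested comparison")
    dchi = max(2.0 * (free.loglik - constrained.loglik), 0.0)
    p = float(stats.chi2.sf(dchi, ddf)) if ddf > 0 else 1.0
    return ComparisonResult(
        delta_chisq=dchi, delta_df=int(ddf), pvalue=p,
        delta_aic=constrained.aic - free.aic,
        delta_sabic=constrained.sabic - free.sabic)


# ---------------------------------------------------------------------------
# Small statistical utilities
# ---------------------------------------------------------------------------

def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def congruence(x, y) -> float:
    """Tucker's coefficient of factor congruence between two loading
    vectors: sum(x*y) / sqrt(sum(x^2) * sum(y^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("loading vectors must have equal length")
    nx, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny_ == 0:
        raise ValueError("zero loading vector")
    return float(x @ y / (nx * ny_))


def pca_first_component(data):
    """First unrotated principal component of the correlation matrix.

    Complete cases only.  Returns ``(loadings, proportion)`` where loadings
    are the first eigenvector scaled to component loadings (eigvec *
    sqrt(eigval)), sign-fixed so that the majority are positive, and
    proportion is the variance share lambda_1 / p.
    """
    X = pd.DataFrame(data).dropna().to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >=2 complete cases and >=2 variables")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant variable in PCA input")
    R = np.corrcoef(X, rowvar=False)
    R = np.nan_to_num(R, nan=1.0)  # perfectly collinear columns
    w, V = np.linalg.eigh(R)
    lam1 = w[-1]
    vec = V[:, -1]
    if np.sum(vec > 0) < np.sum(vec < 0):
        vec = -vec
    return vec * math.sqrt(max(lam1, 0.0)), float(lam1 / R.shape[0])
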