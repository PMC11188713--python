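"""Neural posterior estimation of the network parameters (G_I, G_E).

A conditional Gaussian-mixture density estimator (mixture density network,
MDN) maps the three raster summary features to a posterior density over the
two network parameters.  The network body is a small tanh MLP; its heads
emit mixture logits, component means and per-dimension log-SDs.  Training
minimizes the negative log-likelihood of the (parameter, feature) training
pairs — the standard neural-posterior-estimation objective with samples
drawn from the uniform prior over the box
[0.002, 0.02] x [0, 2e-5].

Because the loss surface depends on initialization, the estimator is
trained repeatedly (default thirty restarts), each restart scoring itself
on its own randomly held-out simulations via the weighted squared error

    (G_I* - G_I)^2 + 900^2 (G_E* - G_E)^2

(the factor 900 compensates the different parameter scales); the restart
with the lowest holdout score wins.  Point estimates are grid maxima (MAP)
of the joint posterior evaluated on a 200 x 200 grid over the prior box;
marginal peaks are also reported.

Features are z-scored with training-set moments and parameters min-max
scaled to the prior box; both transforms are stored with the estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import PRIOR_BOX

MSE_EXCITATION_WEIGHT = 900.0
LOG2PI = np.log(2.0 * np.pi)


@dataclass
class InferenceConfig:
    prior_box: tuple = PRIOR_BOX
    n_restarts: int = 30
    holdout: int = 20
    mse_weight: float = MSE_EXCITATION_WEIGHT
    n_samples: int = 1_000_000
    n_components: int = 8
    hidden: int = 64
    n_layers: int = 2
    epochs: int = 500
    lr: float = 5e-3
    val_frac: float = 0.10
    patience: int = 50
    grid: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.holdout < 0:
            raise ValueError("holdout must be >= 0")


class TrainingError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


def weighted_mse(true_params, est_params, weight: float = MSE_EXCITATION_WEIGHT) -> float:
    """Scale-compensated squared parameter error (symmetric, >= 0)."""
    dgi = est_params[0] - true_params[0]
    dge = est_params[1] - true_params[1]
    return float(dgi * dgi + (weight * dge) ** 2)


def _records_to_arrays(records):
    """Accept (theta, X) arrays or a list of (params, FeatureVector, ...) triples."""
    if isinstance(records, tuple) and len(records) == 2:
        theta, x = records
        return np.asarray(theta, float), np.asarray(x, float)
    theta = np.array([np.asarray(r[0], float) for r in records])
    x = np.array([r[1].as_array() for r in records])
    return theta, x


class MDNEstimator:
    """Conditional Gaussian-mixture density estimator q(theta | features)."""

    def __init__(self, cfg: InferenceConfig, rng: np.random.Generator):
        self.cfg = cfg
        k, h, d_in, d_out = cfg.n_components, cfg.hidden, 3, 2
        self.k, self.d_out = k, d_out

        def init(shape, scale):
            return rng.normal(0.0, scale, shape)

        self.w1 = init((h, d_in), 1.0 / np.sqrt(d_in))
        self.b1 = np.zeros(h)
        self.w2 = init((h, h), 1.0 / np.sqrt(h))
        self.b2 = np.zeros(h)
        self.wa = init((k, h), 0.01)
        self.ba = np.zeros(k)
        self.wm = init((k * d_out, h), 0.01)
        self.bm = rng.uniform(0.1, 0.9, k * d_out)  # spread means over the box
        self.ws = init((k * d_out, h), 0.01)
        self.bs = np.full(k * d_out, np.log(0.25))
        self.x_mean = np.zeros(3)
        self.x_std = np.ones(3)
        self.out_of_support_sd = 3.0

    # ---- transforms -------------------------------------------------
    def _scale_x(self, x):
        return (x - self.x_mean) / self.x_std

    def _scale_theta(self, theta):
        (gi_lo, gi_hi), (ge_lo, ge_hi) = self.cfg.prior_box
        out = np.empty_like(np.asarray(theta, float))
        out[..., 0] = (theta[..., 0] - gi_lo) / (gi_hi - gi_lo)
        out[..., 1] = (theta[..., 1] - ge_lo) / (ge_hi - ge_lo)
        return out

    def _unscale_theta(self, u):
        (gi_lo, gi_hi), (ge_lo, ge_hi) = self.cfg.prior_box
        out = np.empty_like(u)
        out[..., 0] = gi_lo + u[..., 0] * (gi_hi - gi_lo)
        out[..., 1] = ge_lo + u[..., 1] * (ge_hi - ge_lo)
        return out

    # ---- forward ----------------------------------------------------
    def _forward(self, xs):
        z1 = xs @ self.w1.T + self.b1
        h1 = np.tanh(z1)
        z2 = h1 @ self.w2.T + self.b2
        h2 = np.tanh(z2)
        logits = h2 @ self.wa.T + self.ba
        mu = (h2 @ self.wm.T + self.bm).reshape(-1, self.k, self.d_out)
        log_sig = np.clip(h2 @ self.ws.T + self.bs, -7.0, 2.0)
        log_sig = log_sig.reshape(-1, self.k, self.d_out)
        return h1, h2, logits, mu, log_sig

    def mixture_params(self, features):
        """(weights, means, SDs) of the conditional mixture, in scaled space."""
        xs = np.atleast_2d(self._scale_x(np.asarray(features, float)))
        _, _, logits, mu, log_sig = self._forward(xs)
        w = np.exp(logits - logits.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        return w, mu, np.exp(log_sig)

    def log_prob(self, features, theta):
        """log q(theta | features) in scaled parameter space."""
        w, mu, sig = self.mixture_params(features)
        u = np.atleast_2d(self._scale_theta(np.asarray(theta, float)))
        z = (u[:, None, :] - mu) / sig
        comp = -0.5 * (z * z).sum(-1) - np.log(sig).sum(-1) - self.d_out / 2 * LOG2PI
        a = np.log(w + 1e-300) + comp
        m = a.max(axis=1)
        return m + np.log(np.exp(a - m[:, None]).sum(axis=1))

    # ---- training ---------------------------------------------------
    def _loss_grad(self, xs, u):
        n = xs.shape[0]
        h1, h2, logits, mu, log_sig = self._forward(xs)
        sig = np.exp(log_sig)
        z = (u[:, None, :] - mu) / sig
        comp = -0.5 * (z * z).sum(-1) - log_sig.sum(-1) - self.d_out / 2 * LOG2PI
        a = logits - logits.max(axis=1, keepdims=True)
        log_pi = a - np.log(np.exp(a).sum(axis=1, keepdims=True))
        joint = log_pi + comp
        m = joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        loss = -lse.mean()

        r = np.exp(joint - lse[:, None])  # responsibilities
        pi = np.exp(log_pi)
        d_logits = (pi - r) / n
        d_mu = -r[:, :, None] * z / sig / n
        d_ls = -r[:, :, None] * (z * z - 1.0) / n
        # clip mask of log_sig
        raw = (h2 @ self.ws.T + self.bs).reshape(-1, self.k, self.d_out)
        d_ls = d_ls * ((raw > -7.0) & (raw < 2.0))

        d_mu_f = d_mu.reshape(n, -1)
        d_ls_f = d_ls.reshape(n, -1)
        g = {}
        g["wa"] = d_logits.T @ h2
        g["ba"] = d_logits.sum(0)
        g["wm"] = d_mu_f.T @ h2
        g["bm"] = d_mu_f.sum(0)
        g["ws"] = d_ls_f.T @ h2
        g["bs"] = d_ls_f.sum(0)
        d_h2 = d_logits @ self.wa + d_mu_f @ self.wm + d_ls_f @ self.ws
        d_z2 = d_h2 * (1.0 - h2 * h2)
        g["w2"] = d_z2.T @ h1
        g["b2"] = d_z2.sum(0)
        d_h1 = d_z2 @ self.w2
        d_z1 = d_h1 * (1.0 - h1 * h1)
        g["w1"] = d_z1.T @ xs
        g["b1"] = d_z1.sum(0)
        return loss, g

    _PARAMS = ("w1", "b1", "w2", "b2", "wa", "ba", "wm", "bm", "ws", "bs")

    def fit(self, theta, x, rng: np.random.Generator):
        cfg = self.cfg
        self.x_mean = x.mean(axis=0)
        self.x_std = np.where(x.std(axis=0) > 1e-12, x.std(axis=0), 1.0)
        xs = self._scale_x(x)
        u = self._scale_theta(theta)

        n = xs.shape[0]
        n_val = max(1, int(round(cfg.val_frac * n))) if n >= 10 else 0
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        xt, ut = xs[tr_idx], u[tr_idx]
        xv, uv = xs[val_idx], u[val_idx]

        mom1 = {p: np.zeros_like(getattr(self, p)) for p in self._PARAMS}
        mom2 = {p: np.zeros_like(getattr(self, p)) for p in self._PARAMS}
        b1m, b2m, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_state = None
        bad = 0
        for epoch in range(1, cfg.epochs + 1):
            loss, g = self._loss_grad(xt, ut)
            if not np.isfinite(loss):
                raise TrainingError(epoch)
            for p in self._PARAMS:
                mom1[p] = b1m * mom1[p] + (1 - b1m) * g[p]
                mom2[p] = b2m * mom2[p] + (1 - b2m) * g[p] ** 2
                m_hat = mom1[p] / (1 - b1m**epoch)
                v_hat = mom2[p] / (1 - b2m**epoch)
                setattr(self, p, getattr(self, p) - cfg.lr * m_hat / (np.sqrt(v_hat) + eps))
            if n_val:
                vl, _ = self._loss_grad(xv, uv)
                if vl < best_val - 1e-6:
                    best_val = vl
                    best_state = {p: getattr(self, p).copy() for p in self._PARAMS}
                    bad = 0
                else:
                    bad += 1
                    if bad >= cfg.patience:
                        break
        if best_state is not None:
            for p, v in best_state.items():
                setattr(self, p, v)
        return self

    # ---- sampling / persistence ------------------------------------
    def sample(self, features, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw posterior samples (physical units), rejecting outside the box."""
        w, mu, sig = self.mixture_params(features)
        w, mu, sig = w[0], mu[0], sig[0]
        out = np.empty((0, 2))
        while out.shape[0] < n:
            m = max(n - out.shape[0], 1024)
            comp = rng.choice(self.k, size=m, p=w)
            u = mu[comp] + sig[comp] * rng.standard_normal((m, 2))
            ok = (u >= 0.0).all(axis=1) & (u <= 1.0).all(axis=1)
            out = np.vstack([out, self._unscale_theta(u[ok])])
        return out[:n]

    def to_dict(self) -> dict:
        d = {p: getattr(self, p).tolist() for p in self._PARAMS}
        d["x_mean"] = self.x_mean.tolist()
        d["x_std"] = self.x_std.tolist()
        d["config"] = {
            "n_components": self.cfg.n_components,
            "hidden": self.cfg.hidden,
            "prior_box": [list(b) for b in self.cfg.prior_box],
        }
        return d

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        cfg = InferenceConfig(
            n_components=d["config"]["n_components"],
            hidden=d["config"]["hidden"],
            prior_box=tuple(tuple(b) for b in d["config"]["prior_box"]),
        )
        est = cls(cfg, np.random.default_rng(0))
        for p in cls._PARAMS:
            setattr(est, p, np.array(d[p]))
        est.x_mean = np.array(d["x_mean"])
        est.x_std = np.array(d["x_std"])
        return est


@dataclass
class PosteriorSummary:
    """Posterior density over (G_I, G_E): grids, marginals, point estimates."""

    gi_grid: np.ndarray
    ge_grid: np.ndarray
    joint: np.ndarray  # (grid, grid) density, normalized over the box
    marginal_gi: np.ndarray
    marginal_ge: np.ndarray
    map_gi: float
    map_ge: float
    marginal_peak_gi: float
    marginal_peak_ge: float
    samples: np.ndarray | None = None
    out_of_support: bool = False

    @property
    def map_params(self) -> tuple[float, float]:
        return self.map_gi, self.map_ge


def train_estimator(records, cfg: InferenceConfig, seed: int = 0) -> MDNEstimator:
    """Fit one MDN on filtered (parameter, feature) records by NLL descent."""
    theta, x = _records_to_arrays(records)
    if theta.shape[0] < 2:
        raise ValueError("need at least two training records")
    rng = np.random.default_rng(seed)
    est = MDNEstimator(cfg, rng)
    return est.fit(theta, x, rng)


def posterior_map(
    estimator: MDNEstimator,
    features,
    cfg: InferenceConfig | None = None,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> PosteriorSummary:
    """Posterior summary for one feature vector.

    The joint density is evaluated on a grid over the prior box (grid cells
    at bin centers) and normalized there; the MAP is the grid argmax and
    marginals are grid sums.  Samples are drawn only when ``n_samples`` > 0.
    """
    cfg = cfg or estimator.cfg
    if hasattr(features, "as_array"):
        features = features.as_array()
    features = np.asarray(features, float)
    g = cfg.grid
    (gi_lo, gi_hi), (ge_lo, ge_hi) = cfg.prior_box
    gi = gi_lo + (np.arange(g) + 0.5) / g * (gi_hi - gi_lo)
    ge = ge_lo + (np.arange(g) + 0.5) / g * (ge_hi - ge_lo)
    gg, ee = np.meshgrid(gi, ge, indexing="ij")
    pts = np.column_stack([gg.ravel(), ee.ravel()])
    # evaluate the conditional mixture once, then the density on the grid
    w, mu, sig = estimator.mixture_params(features)
    u = estimator._scale_theta(pts)
    z = (u[:, None, :] - mu[0]) / sig[0]
    comp = -0.5 * (z * z).sum(-1) - np.log(sig[0]).sum(-1) - LOG2PI
    a = np.log(w[0] + 1e-300) + comp
    logp = a.max(axis=1) + np.log(
        np.exp(a - a.max(axis=1, keepdims=True)).sum(axis=1))
    joint = np.exp(logp - logp.max()).reshape(g, g)
    cell = ((gi_hi - gi_lo) / g) * ((ge_hi - ge_lo) / g)
    joint = joint / (joint.sum() * cell)
    i, j = np.unravel_index(np.argmax(joint), joint.shape)
    marg_gi = joint.sum(axis=1) * (ge_hi - ge_lo) / g
    marg_ge = joint.sum(axis=0) * (gi_hi - gi_lo) / g
    xs = estimator._scale_x(features)
    oos = bool(np.any(np.abs(xs) > estimator.out_of_support_sd))
    samples = None
    n_samples = cfg.n_samples if n_samples is None else n_samples
    if n_samples and rng is not None:
        samples = estimator.sample(features, int(n_samples), rng)
    return PosteriorSummary(
        gi_grid=gi, ge_grid=ge, joint=joint,
        marginal_gi=marg_gi, marginal_ge=marg_ge,
        map_gi=float(gi[i]), map_ge=float(ge[j]),
        marginal_peak_gi=float(gi[np.argmax(marg_gi)]),
        marginal_peak_ge=float(ge[np.argmax(marg_ge)]),
        samples=samples, out_of_support=oos,
    )


@dataclass
class RestartResult:
    estimator: MDNEstimator
    holdout_mse: float
    restart_index: int
    holdout_idx: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def _holdout_mse(est, theta_h, x_h, cfg) -> float:
    errs = []
    for th, xh in zip(theta_h, x_h):
        summ = posterior_map(est, xh, cfg, n_samples=0)
        errs.append(weighted_mse(th, summ.map_params, cfg.mse_weight))
    return float(np.mean(errs))


def train_restarts(records, cfg: InferenceConfig, seed: int | None = None):
    """Train ``n_restarts`` estimators, each scored on its own random holdout."""
    theta, x = _records_to_arrays(records)
    n = theta.shape[0]
    if cfg.holdout >= n:
        raise ValueError("holdout must be smaller than the number of records")
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    results = []
    for k in range(cfg.n_restarts):
        rs = master.integers(0, 2**31 - 1)
        rng = np.random.default_rng(rs)
        idx = rng.permutation(n)
        hold, tr = idx[: cfg.holdout], idx[cfg.holdout:]
        est = train_estimator((theta[tr], x[tr]), cfg, seed=int(rs))
        mse = _holdout_mse(est, theta[hold], x[hold], cfg) if hold.size else np.inf
        results.append(RestartResult(est, mse, k, hold))
    return results


def select_winner(results: list[RestartResult]) -> RestartResult:
    """Restart with minimum holdout weighted MSE; ties break by index."""
    if not results:
        raise ValueError("no restart results")
    best = results[0]
    for r in results[1:]:
        if r.holdout_mse < best.holdout_mse:
            best = r
    return best


def best_fit_lookup(target, records):
    """Record whose parameters minimize the weighted MSE to ``target``.

    Ties break toward the lowest record index.
    """
    theta, _ = _records_to_arrays(records)
    if theta.shape[0] == 0:
        raise ValueError("no records")
    errs = [weighted_mse(t, target) for t in theta]
    i = int(np.argmin(errs))
    return i, (records[i] if not isinstance(records, tuple) else theta[i])
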