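"""Deep lifetime clustering (DLC): a feed-forward network whose softmax
output assigns each patient to one of K clusters, trained to maximize
the *minimum* pairwise divergence between the clusters' soft-weighted
Kaplan-Meier curves.

The divergence is either the negative log of the Kuiper two-sample
p-value upper bound (default) or the squared maximum mean discrepancy
over follow-up times.  A quadratic hinge penalty on small cluster mass
fractions guards against cluster collapse.  The terminating-signal
branch of the original framework is deliberately absent: event
indicators are observed here, so only the assignment network is learned.

Training is full-batch gradient ascent (Adam) through the package's own
reverse-mode autodiff; the whole objective — softmax, product-limit
curves, divergence, penalty — is piecewise smooth, and reductions use
the argmax subgradient.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, stack
from .survival import DivergenceSpec, KUIPER_P_FLOOR, km_estimate

__all__ = [
    "SoftAssignment",
    "HyperparameterGrid",
    "DLCModel",
    "dlc_loss",
    "dlc_loss_grad",
    "dlc_fit",
    "dlc_predict",
    "order_clusters_by_risk",
]

# (minimum mass fraction, penalty strength): the hinge must compete with
# divergences measured in tens of log-units, so the strength is large
DEFAULT_BALANCE = (0.05, 2.0e4)
_EPS = 1e-12


@dataclass(frozen=True)
class SoftAssignment:
    """Row-stochastic n x K cluster membership matrix."""

    q: np.ndarray
    hard_labels: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q)
        if q.ndim != 2 or q.shape[1] < 2:
            raise ValueError("q must be n x K with K >= 2")
        if np.any(q < -1e-9):
            raise ValueError("memberships must be non-negative")
        if np.max(np.abs(q.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("membership rows must sum to 1")


@dataclass(frozen=True)
class HyperparameterGrid:
    """Search space for the network fit; the cross product is explored
    and the winner picked on the validation split."""

    n_layers: tuple = (0, 1, 2)
    hidden_width: tuple = (16, 32)
    learning_rate: tuple = (1e-3, 1e-2)
    activation: tuple = ("relu", "tanh")
    epochs: int = 300
    n_restarts: int = 1
    selection_metric: str = "validation_logrank"

    def __post_init__(self):
        if not (self.n_layers and self.hidden_width and self.learning_rate
                and self.activation):
            raise ValueError("grid sets must be non-empty")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.selection_metric not in ("validation_logrank",
                                         "validation_divergence"):
            raise ValueError("unknown selection metric "
                             f"{self.selection_metric!r}")

    def points(self):
        pts = list(itertools.product(self.n_layers, self.hidden_width,
                                     self.learning_rate, self.activation))
        return pts * self.n_restarts


# ---------------------------------------------------------------------------
# loss graph
# ---------------------------------------------------------------------------

class _LossContext:
    """Precomputed fixed structure of the objective for one dataset.

    E[i, l] = 1 if row i has the event exactly at distinct event time l;
    R[i, l] = 1 if row i is still at risk just before time l.  The soft
    KM curve of cluster k then needs only the two matrix products E'q_k
    and R'q_k per evaluation.
    """

    def __init__(self, times, events, divergence: DivergenceSpec,
                 balance=DEFAULT_BALANCE):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events).astype(bool)
        if events.sum() == 0:
            raise ValueError("objective needs at least one event")
        self.n = times.size
        self.uniq = np.unique(times[events])
        self.E = ((times[:, None] == self.uniq[None, :])
                  & events[:, None]).astype(float)
        self.R = (times[:, None] >= self.uniq[None, :]).astype(float)
        self.divergence = divergence
        self.m_min, self.rho = balance
        self.kernel = None
        if divergence.kind == "mmd":
            diffs = times[:, None] - times[None, :]
            bw = divergence.mmd_bandwidth
            if bw == "median-heuristic":
                iu = np.triu_indices(self.n, k=1)
                bw = float(np.median(np.abs(diffs[iu]))) or 1.0
            self.kernel = Tensor(np.exp(-(diffs**2) / (2.0 * float(bw)**2)))
        self._E_t = Tensor(self.E.T)
        self._R_t = Tensor(self.R.T)

    def _soft_km(self, q: Tensor) -> Tensor:
        """m x K matrix of per-cluster soft survival curves."""
        d = self._E_t @ q
        n_at = (self._R_t @ q).maximum(_EPS)
        haz = (d / n_at).clip(0.0, 1.0 - 1e-9)
        return ((1.0 - haz).log().cumsum(axis=0)).exp()

    # The leading term of the Kuiper tail series is negative below
    # lambda = 1/2 and rises to its maximum at lambda = sqrt(3)/2 before
    # decaying, so -log(term) is not monotone in V there and carries no
    # usable gradient for barely-separated clusters.  The trainable
    # divergence therefore uses the decreasing branch only (shifted so
    # identical curves give exactly 0) and max-combines it with a gentle
    # capped quadratic ramp in lambda that supplies gradient below the
    # peak; the result is monotone in V, symmetric, and >= 0.
    _LAM_PEAK = np.sqrt(3.0) / 2.0
    _LOG_P_PEAK = float(np.log(4.0 * np.exp(-1.5)))
    _RAMP_SLOPE = 0.2

    def _kuiper_delta(self, s: Tensor, w: Tensor, i: int, j: int) -> Tensor:
        diff = s[:, i] - s[:, j]
        v = diff.max().maximum(0.0) + (-diff).max().maximum(0.0)
        n_e = w[i] * w[j] / (w[i] + w[j])
        root = n_e**0.5
        lam = (root + 0.155 + 0.24 / root) * v
        lam_tail = lam.maximum(self._LAM_PEAK)
        p = (2.0 * (4.0 * lam_tail * lam_tail - 1.0)
             * (-2.0 * lam_tail * lam_tail).exp())
        log_p = p.clip(self.divergence.kuiper_clamp, 1.0).log()
        tail = (self._LOG_P_PEAK - log_p).maximum(0.0)
        ramp = (self._RAMP_SLOPE * lam * lam).clip(None, 1.0)
        # elementwise max of two scalars via max-reduce over a stack
        return stack([tail, ramp]).max()

    def loss(self, q: Tensor) -> Tensor:
        """-min pairwise divergence + balance penalty (lower = better)."""
        k = q.data.shape[1]
        w = q.sum(axis=0)
        event_mass = self.E.T @ q.data  # numpy: which clusters carry events
        cluster_has_events = event_mass.sum(axis=0) > 1e-9
        deltas = []
        if self.divergence.kind == "kuiper_ub":
            s = self._soft_km(q)
            gram = None
        else:
            qn = q / w
            kq = self.kernel @ qn
            gram = qn.T @ kq
        for i in range(k):
            for j in range(i + 1, k):
                if not (cluster_has_events[i] and cluster_has_events[j]):
                    # no separation evidence from an event-free cluster
                    deltas.append(Tensor(0.0))
                elif gram is None:
                    deltas.append(self._kuiper_delta(s, w, i, j))
                else:
                    deltas.append(gram[i, i] + gram[j, j] - 2.0 * gram[i, j])
        min_delta = stack(deltas).min()
        frac = w * (1.0 / self.n)
        penalty = self.rho * ((-(frac - self.m_min)).maximum(0.0)**2).sum()
        return -min_delta + penalty


def dlc_loss(q, times, events, divergence: DivergenceSpec | None = None,
             balance=DEFAULT_BALANCE) -> float:
    """Clustering objective value for a fixed soft assignment."""
    divergence = divergence or DivergenceSpec()
    ctx = _LossContext(times, events, divergence, balance)
    return ctx.loss(Tensor(np.asarray(q, float))).item()


def dlc_loss_grad(q, times, events, divergence: DivergenceSpec | None = None,
                  balance=DEFAULT_BALANCE) -> tuple[float, np.ndarray]:
    """Objective value and its gradient with respect to q."""
    divergence = divergence or DivergenceSpec()
    ctx = _LossContext(times, events, divergence, balance)
    qt = Tensor(np.asarray(q, float), requires_grad=True)
    out = ctx.loss(qt)
    out.backward()
    return out.item(), qt.grad


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _init_params(d_in: int, widths: list[int], k: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """Xavier-uniform weights and zero biases, flattened as [W, b, ...]."""
    sizes = [d_in] + widths + [k]
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        params.append(rng.uniform(-lim, lim, size=(fan_in, fan_out)))
        params.append(np.zeros(fan_out))
    return params


def _forward(params: list[Tensor], x: Tensor, activation: str) -> Tensor:
    h = x
    n_layers = len(params) // 2
    for layer in range(n_layers):
        h = h @ params[2 * layer] + params[2 * layer + 1]
        if layer < n_layers - 1:
            h = h.tanh() if activation == "tanh" else h.relu()
    return h.softmax(axis=1)


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: list[Tensor]):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, p in enumerate(params):
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + eps)
            p.grad = None


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class DLCModel:
    """A fitted lifetime-clustering network.

    ``risk_order[raw_cluster] = rank`` with rank 0 the highest-risk
    cluster, so reported labels are comparable across fits.
    """

    weights: list[np.ndarray]
    widths: list[int]
    activation: str
    divergence: DivergenceSpec
    n_clusters: int
    balance: tuple = DEFAULT_BALANCE
    risk_order: np.ndarray | None = None
    preprocessing_state: object = None
    selected_config: dict = field(default_factory=dict)

    def predict_soft(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match the model "
                f"({self.weights[0].shape[0]})")
        params = [Tensor(w) for w in self.weights]
        return _forward(params, Tensor(x), self.activation).data

    def predict(self, x: np.ndarray) -> SoftAssignment:
        q = self.predict_soft(x)
        raw = q.argmax(axis=1)
        labels = (self.risk_order[raw] if self.risk_order is not None
                  else raw)
        return SoftAssignment(q, labels)

    def save(self, path) -> None:
        payload = {
            "weights": [w.tolist() for w in self.weights],
            "widths": self.widths,
            "activation": self.activation,
            "divergence": {"kind": self.divergence.kind,
                           "mmd_bandwidth": self.divergence.mmd_bandwidth},
            "n_clusters": self.n_clusters,
            "balance": list(self.balance),
            "risk_order": (self.risk_order.tolist()
                           if self.risk_order is not None else None),
            "selected_config": self.selected_config,
        }
        if self.preprocessing_state is not None:
            payload["transform"] = {
                "medians": self.preprocessing_state.medians,
                "minmax": {k: list(v) for k, v
                           in self.preprocessing_state.minmax.items()},
                "levels": self.preprocessing_state.levels,
                "feature_names":
                    list(self.preprocessing_state.feature_names),
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DLCModel":
        from .preprocess import TransformState

        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        state = None
        if "transform" in d:
            t = d["transform"]
            state = TransformState(
                t["medians"],
                {k: tuple(v) for k, v in t["minmax"].items()},
                t["levels"], tuple(t["feature_names"]))
        return cls(
            weights=[np.asarray(w) for w in d["weights"]],
            widths=list(d["widths"]),
            activation=d["activation"],
            divergence=DivergenceSpec(d["divergence"]["kind"],
                                      d["divergence"]["mmd_bandwidth"]),
            n_clusters=d["n_clusters"],
            balance=tuple(d["balance"]),
            risk_order=(np.asarray(d["risk_order"])
                        if d["risk_order"] is not None else None),
            preprocessing_state=state,
            selected_config=d.get("selected_config", {}),
        )


def order_clusters_by_risk(labels, times, events, n_clusters=None,
                           horizon: float = 365.0) -> np.ndarray:
    """Permutation mapping raw cluster index -> risk rank (0 = highest).

    Clusters are ranked by their one-year KM cumulative event
    probability, descending; ties broken by cluster size, descending.
    Empty clusters (only possible for a degenerate fit) rank last.
    """
    labels = np.asarray(labels)
    k = int(n_clusters if n_clusters is not None else labels.max() + 1)
    keys = []
    for c in range(k):
        mask = labels == c
        if not mask.any():
            keys.append((np.inf, 0, c))
            continue
        curve = km_estimate(np.asarray(times)[mask],
                            np.asarray(events)[mask])
        event_prob = 1.0 - float(curve.survival_at(horizon))
        keys.append((-event_prob, -int(mask.sum()), c))
    ranked = sorted(range(k), key=lambda c: keys[c])
    perm = np.empty(k, dtype=int)
    for rank, raw in enumerate(ranked):
        perm[raw] = rank
    return perm


def _selection_score(model_q: np.ndarray, times, events, ctx: _LossContext,
                     metric: str) -> float:
    """Higher = better candidate (validation separation)."""
    if metric == "validation_divergence":
        return -ctx.loss(Tensor(model_q)).item()
    labels = model_q.argmax(axis=1)
    present = np.unique(labels)
    if present.size < 2 or np.asarray(events)[np.isin(labels, present)].sum() == 0:
        return -np.inf
    from .survival import logrank_statistic

    try:
        return logrank_statistic(times, events, labels)
    except ValueError:
        return -np.inf


def dlc_fit(train_x, train_times, train_events, val_x, val_times, val_events,
            grid: HyperparameterGrid | None = None,
            divergence: DivergenceSpec | None = None,
            n_clusters: int = 3, balance=DEFAULT_BALANCE, seed: int = 0,
            batch_size: int | None = None) -> DLCModel:
    """Grid-search fit of the lifetime-clustering network.

    Each grid point trains from a seed-derived initialization with
    full-batch Adam (or mini-batches of ``batch_size`` >= 512); the
    candidate with the best validation selection metric wins.  Returns
    the winning model with its risk ordering computed on training data.
    """
    grid = grid or HyperparameterGrid()
    divergence = divergence or DivergenceSpec()
    train_x = np.asarray(train_x, dtype=float)
    train_events = np.asarray(train_events).astype(int)
    if train_x.shape[0] < n_clusters * 20:
        raise ValueError("training split too small for the cluster count")
    if train_events.sum() < n_clusters:
        raise ValueError("training split needs at least K events")
    if batch_size is not None and batch_size < 512:
        raise ValueError("mini-batches below 512 rows are not supported")

    full_ctx = _LossContext(train_times, train_events, divergence, balance)
    val_ctx = _LossContext(val_times, val_events, divergence, balance)
    val_xt = Tensor(np.asarray(val_x, float))
    check_every = 10  # validation-selection checkpoint interval
    mass_floor = balance[0] * train_x.shape[0] / 2.0
    best = None
    for idx, (layers, width, lr, act) in enumerate(grid.points()):
        rng = np.random.default_rng([seed, idx])
        raw = _init_params(train_x.shape[1], [width] * layers, n_clusters,
                           rng)
        params = [Tensor(p, requires_grad=True) for p in raw]
        opt = _Adam([p.shape for p in raw], lr)
        xt = Tensor(train_x)
        for epoch in range(grid.epochs):
            if batch_size is None:
                q = _forward(params, xt, act)
                loss = full_ctx.loss(q)
            else:
                take = rng.choice(train_x.shape[0],
                                  size=min(batch_size, train_x.shape[0]),
                                  replace=False)
                ctx = _LossContext(np.asarray(train_times)[take],
                                   train_events[take], divergence, balance)
                q = _forward(params, Tensor(train_x[take]), act)
                loss = ctx.loss(q)
            loss.backward()
            opt.step(params)
            if (epoch + 1) % check_every and epoch + 1 != grid.epochs:
                continue
            # checkpoint: keep the parameters with the best validation
            # selection metric, across epochs and grid points alike
            masses = _forward(params, xt, act).data.sum(axis=0)
            if masses.min() < mass_floor:
                continue  # collapsed at this checkpoint
            q_val = _forward(params, val_xt, act).data
            score = _selection_score(q_val, val_times, val_events, val_ctx,
                                     grid.selection_metric)
            if best is None or score > best[0]:
                best = (score, [p.data.copy() for p in params],
                        {"n_layers": layers, "hidden_width": width,
                         "learning_rate": lr, "activation": act,
                         "grid_index": idx, "epoch": epoch + 1})
    if best is None:
        raise ValueError("every grid point collapsed a cluster below the "
                         "minimum mass; increase the balance penalty rho")
    _, weights, config = best
    model = DLCModel(weights=weights,
                     widths=[config["hidden_width"]] * config["n_layers"],
                     activation=config["activation"], divergence=divergence,
                     n_clusters=n_clusters, balance=tuple(balance),
                     selected_config=config)
    hard = model.predict_soft(train_x).argmax(axis=1)
    model.risk_order = order_clusters_by_risk(hard, train_times,
                                              train_events,
                                              n_clusters=n_clusters)
    return model


def dlc_predict(model: DLCModel, x) -> SoftAssignment:
    """Soft memberships plus risk-ordered hard labels for new rows."""
    return model.predict(np.asarray(x, dtype=float))
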