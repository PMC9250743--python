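"""Unsupervised phase extraction from quasi-periodic multi-channel windows.

A short sliding window of the (AZEQ-flattened, standardized) feature stream
is mapped to a point on the unit circle; the angle phi = atan2(y, x) mod 2*pi
is the movement phase.  Two extractors satisfy the same contract — on clean
quasi-periodic data the extracted angle tracks the latent cycle with high
circular correlation after a global direction/offset calibration:

* ``pca``: a deterministic linear extractor — each window is projected onto
  the two leading (whitened) principal components of the training windows
  and the angle in that plane is the phase.  For signals with a dominant
  fundamental the top two components approximate the quadrature pair
  (cos phi, sin phi), so the planar angle is a monotone reparametrization of
  the cycle.
* ``network``: a small fully connected network (default 5 hidden layers of
  30 tanh units, two linear outputs) trained without labels.  Training first
  regresses the network onto the PCA extractor's circle points
  (self-supervised initialization), then fine-tunes with a relational
  objective on consecutive window pairs: outputs are pulled to unit norm,
  the angular increment between consecutive windows is pushed to be
  non-negative and near-constant, and a batch-level coverage penalty keeps
  the angle distribution spread over the circle (guarding against phase
  collapse).

The learned phase has an arbitrary global offset and direction; the offset is
harmless downstream (circular DTW is offset-free) and the direction is fixed
by :func:`calibrate_direction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PhaseHyperparams",
    "PhaseNetwork",
    "PhaseSequence",
    "build_window_pairs",
    "build_windows",
    "train_phase_network",
    "train_fallback_extractor",
    "calibrate_direction",
    "extract_phase",
    "smooth_phase",
    "circular_correlation",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhaseHyperparams:
    window_len: int = 7
    hidden: tuple[int, ...] = (30, 30, 30, 30, 30)
    pretrain_iters: int = 1500
    finetune_iters: int = 400
    batch_size: int = 256
    learning_rate: float = 1e-3
    max_windows: int = 20000
    w_norm: float = 1.0
    w_forward: float = 4.0
    w_var: float = 1.0
    w_cover: float = 1.0


@dataclass
class PhaseSequence:
    circle: np.ndarray  # (T, 2) points on the unit circle

    def __post_init__(self):
        self.circle = np.asarray(self.circle, dtype=float)

    @property
    def angles(self) -> np.ndarray:
        """phi = atan2(y, x) mod 2*pi, in [0, 2*pi)."""
        return np.mod(np.arctan2(self.circle[:, 1], self.circle[:, 0]), TWO_PI)

    def __len__(self):
        return self.circle.shape[0]


def build_windows(features: np.ndarray, window_len: int) -> np.ndarray:
    """All length-``window_len`` windows, flattened sample-major: the window
    starting at t is [x_t, x_{t+1}, ..., x_{t+w-1}] with each sample's dims
    contiguous.  Returns (T - w + 1, w * D)."""
    X = np.asarray(features, dtype=float)
    T, D = X.shape
    w = int(window_len)
    if T < w:
        raise ValueError(f"sequence of length {T} shorter than window {w}")
    idx = np.arange(T - w + 1)[:, None] + np.arange(w)[None, :]
    return X[idx].reshape(T - w + 1, w * D)


def build_window_pairs(features: np.ndarray, window_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Consecutive window pairs (window at t, window at t+1); L - w pairs for
    a length-L sequence (windows overlap by w-1 samples)."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < window_len + 1:
        raise ValueError("sequence too short for a consecutive window pair")
    W = build_windows(X, window_len)
    return W[:-1], W[1:]


# ---------------------------------------------------------------------------
# Small fully connected network with manual backprop (Adam)
# ---------------------------------------------------------------------------


class _MLP:
    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.W = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        acts = [X]
        h = X
        for l, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if l == len(self.W) - 1 else np.tanh(z)
            acts.append(h)
        return acts

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[-1]

    def backward(self, acts: list[np.ndarray], dout: np.ndarray):
        """Gradients of a scalar loss given dL/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for l in range(len(self.W) - 1, -1, -1):
            if l != len(self.W) - 1:
                delta = delta * (1.0 - acts[l + 1] ** 2)  # tanh'
            gW[l] = acts[l].T @ delta
            gb[l] = delta.sum(axis=0)
            delta = delta @ self.W[l].T
        return gW, gb

    def params(self):
        return self.W + self.b

    def to_dict(self) -> dict:
        return {
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_MLP":
        obj = cls.__new__(cls)
        obj.W = [np.asarray(w, dtype=float) for w in d["W"]]
        obj.b = [np.asarray(b, dtype=float) for b in d["b"]]
        return obj


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class PhaseNetwork:
    """A trained phase extractor (neural or PCA fallback) with its input
    standardization and direction calibration."""

    kind: str  # "network" | "pca"
    window_len: int
    feat_mean: np.ndarray  # (D,) per-dimension mean of the flat features
    feat_sd: np.ndarray  # (D,) strictly positive
    flip: bool = False  # negate y output (direction calibration)
    mlp: _MLP | None = None
    pca_mean: np.ndarray | None = None  # (w*D,) window-space mean
    pca_proj: np.ndarray | None = None  # (2, w*D) whitened component rows
    hyperparams: PhaseHyperparams = field(default_factory=PhaseHyperparams)
    train_seed: int | None = None

    def raw_output(self, windows: np.ndarray) -> np.ndarray:
        if self.kind == "network":
            out = self.mlp(windows)
        else:
            out = (windows - self.pca_mean) @ self.pca_proj.T
        if self.flip:
            out = out * np.array([1.0, -1.0])
        return out

    def standardize(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.shape[1] != self.feat_mean.size:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the "
                f"extractor's schema ({self.feat_mean.size} dims)"
            )
        return (X - self.feat_mean) / self.feat_sd


def _standardization(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    allX = np.concatenate(arrays, axis=0)
    mean = allX.mean(axis=0)
    sd = allX.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    return mean, sd


def _collect_windows(arrays, mean, sd, w):
    wins, pair_a, pair_b, off = [], [], [], 0
    for X in arrays:
        Z = (np.asarray(X, dtype=float) - mean) / sd
        Wn = build_windows(Z, w)
        wins.append(Wn)
        k = Wn.shape[0]
        pair_a.append(off + np.arange(k - 1))
        pair_b.append(off + np.arange(1, k))
        off += k
    return np.concatenate(wins), np.concatenate(pair_a), np.concatenate(pair_b)


def train_fallback_extractor(
    training_arrays: list[np.ndarray],
    hyperparams: PhaseHyperparams = PhaseHyperparams(),
    seed: int = 0,
) -> PhaseNetwork:
    """Deterministic linear extractor: angle in the plane of the two leading
    whitened principal components of all training windows."""
    hp = hyperparams
    mean, sd = _standardization(training_arrays)
    windows, _, _ = _collect_windows(training_arrays, mean, sd, hp.window_len)
    rng = np.random.default_rng(seed)
    if windows.shape[0] > hp.max_windows:
        sel = rng.choice(windows.shape[0], hp.max_windows, replace=False)
        windows = windows[np.sort(sel)]
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(windows)
    proj = pca.components_ / np.sqrt(pca.explained_variance_[:, None])
    return PhaseNetwork(
        kind="pca",
        window_len=hp.window_len,
        feat_mean=mean,
        feat_sd=sd,
        pca_mean=pca.mean_.copy(),
        pca_proj=proj,
        hyperparams=hp,
        train_seed=seed,
    )


def _relational_grads(O1, O2, hp):
    """Loss and dL/dO for the consecutive-window relational objective."""
    N = O1.shape[0]
    r1 = np.linalg.norm(O1, axis=1, keepdims=True)
    r2 = np.linalg.norm(O2, axis=1, keepdims=True)
    r1 = np.maximum(r1, 1e-9)
    r2 = np.maximum(r2, 1e-9)
    u1, u2 = O1 / r1, O2 / r2

    # angular increment sine: s = u1 x u2
    s = u1[:, 0] * u2[:, 1] - u1[:, 1] * u2[:, 0]

    # (a) unit-norm regularization
    L_norm = hp.w_norm * (np.mean((r1 - 1) ** 2) + np.mean((r2 - 1) ** 2))
    g1 = hp.w_norm * 2 * (r1 - 1) / N * u1
    g2 = hp.w_norm * 2 * (r2 - 1) / N * u2

    # (b) forward progression: penalize backward steps and increment spread
    neg = np.minimum(s, 0.0)
    L_fwd = hp.w_forward * np.mean(neg**2)
    ds = hp.w_forward * 2 * neg / N
    L_var = hp.w_var * np.var(s)
    ds = ds + hp.w_var * 2 * (s - s.mean()) / N
    du1 = ds[:, None] * np.stack([u2[:, 1], -u2[:, 0]], axis=1)
    du2 = ds[:, None] * np.stack([-u1[:, 1], u1[:, 0]], axis=1)

    # (c) coverage: circle points should spread over the circle
    U = np.concatenate([u1, u2], axis=0)
    mu = U.mean(axis=0)
    M = U.T @ U / (2 * N)
    Mdev = M - 0.5 * np.eye(2)
    L_cov = hp.w_cover * (mu @ mu + np.sum(Mdev**2))
    dU = hp.w_cover * (2 * mu[None, :] / (2 * N) + U @ (4 * Mdev) / (2 * N))
    du1 = du1 + dU[:N]
    du2 = du2 + dU[N:]

    # chain through u = O / r: dO = (I - u u^T)/r du
    def through(u, r, du):
        return (du - (np.sum(du * u, axis=1, keepdims=True)) * u) / r

    dO1 = through(u1, r1, du1) + g1
    dO2 = through(u2, r2, du2) + g2
    loss = L_norm + L_fwd + L_var + L_cov
    return loss, dO1, dO2


def train_phase_network(
    training_arrays: list[np.ndarray],
    hyperparams: PhaseHyperparams = PhaseHyperparams(),
    seed: int = 0,
) -> PhaseNetwork:
    """Train the neural phase extractor (deterministic under ``seed``).

    Inputs are flat feature arrays (T, D) with AZEQ already applied to sphere
    channels.  Training is unsupervised: self-supervised regression onto the
    PCA fallback's circle points, then fine-tuning with the relational
    objective on consecutive window pairs.
    """
    hp = hyperparams
    fallback = train_fallback_extractor(training_arrays, hp, seed)
    mean, sd = fallback.feat_mean, fallback.feat_sd
    windows, pair_a, pair_b = _collect_windows(training_arrays, mean, sd, hp.window_len)
    rng = np.random.default_rng(seed)
    if pair_a.size > hp.max_windows:
        sel = np.sort(rng.choice(pair_a.size, hp.max_windows, replace=False))
        pair_a, pair_b = pair_a[sel], pair_b[sel]

    # pretraining targets: fallback circle points, normalized
    targets = fallback.raw_output(windows)
    targets /= np.maximum(np.linalg.norm(targets, axis=1, keepdims=True), 1e-9)

    mlp = _MLP([windows.shape[1], *hp.hidden, 2], rng)
    opt = _Adam(mlp.params(), lr=hp.learning_rate)
    n_win = windows.shape[0]
    for _ in range(hp.pretrain_iters):
        idx = rng.integers(0, n_win, hp.batch_size)
        acts = mlp.forward(windows[idx])
        out = acts[-1]
        dout = 2 * (out - targets[idx]) / idx.size
        gW, gb = mlp.backward(acts, dout)
        opt.step(mlp.params(), gW + gb)

    opt = _Adam(mlp.params(), lr=hp.learning_rate * 0.3)
    n_pairs = pair_a.size
    for _ in range(hp.finetune_iters):
        idx = rng.integers(0, n_pairs, hp.batch_size)
        a1 = mlp.forward(windows[pair_a[idx]])
        a2 = mlp.forward(windows[pair_b[idx]])
        _, d1, d2 = _relational_grads(a1[-1], a2[-1], hp)
        gW1, gb1 = mlp.backward(a1, d1)
        gW2, gb2 = mlp.backward(a2, d2)
        grads = [x + y for x, y in zip(gW1 + gb1, gW2 + gb2)]
        opt.step(mlp.params(), grads)

    return PhaseNetwork(
        kind="network",
        window_len=hp.window_len,
        feat_mean=mean,
        feat_sd=sd,
        mlp=mlp,
        hyperparams=hp,
        train_seed=seed,
    )


def extract_phase(network: PhaseNetwork, features: np.ndarray) -> PhaseSequence:
    """Per-sample phase on the unit circle.

    Each window's output is assigned to the window's center sample and
    normalized onto the circle; the first/last floor(w/2) samples copy the
    nearest computed value so output length equals input length.
    """
    Z = network.standardize(features)
    W = build_windows(Z, network.window_len)
    out = network.raw_output(W)
    norms = np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-9)
    circle = out / norms
    T = Z.shape[0]
    w = network.window_len
    lead = w // 2
    full = np.empty((T, 2))
    full[lead : lead + circle.shape[0]] = circle
    full[:lead] = circle[0]
    full[lead + circle.shape[0] :] = circle[-1]
    return PhaseSequence(full)


def calibrate_direction(network: PhaseNetwork, reference_features: np.ndarray) -> PhaseNetwork:
    """Orient the extractor so phase advances forward on normal movement.

    If the median angular increment on the reference is negative the y output
    is negated; the global offset is left untouched (downstream matching is
    offset-free).
    """
    seq = extract_phase(network, reference_features)
    ang = seq.angles
    inc = np.mod(np.diff(ang) + np.pi, TWO_PI) - np.pi
    med = np.median(inc)
    if med == 0.0:
        raise ValueError("cannot calibrate: zero median phase increment")
    if med < 0:
        from dataclasses import replace

        return replace(network, flip=not network.flip)
    return network


def smooth_phase(seq: PhaseSequence, window: int = 7) -> PhaseSequence:
    """Centered moving average of the circle points, renormalized to the
    circle; the window shrinks at the edges.  If averaging cancels to (0,0)
    (antipodal samples) the previous smoothed value is kept."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    C = seq.circle
    T = C.shape[0]
    h = window // 2
    out = np.empty_like(C)
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(C, axis=0)])
    for t in range(T):
        a, b = max(0, t - h), min(T, t + h + 1)
        out[t] = (csum[b] - csum[a]) / (b - a)
    norms = np.linalg.norm(out, axis=1)
    bad = norms < 1e-9
    for t in np.nonzero(bad)[0]:
        out[t] = out[t - 1] if t > 0 else C[0]
    norms = np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-300)
    return PhaseSequence(out / norms)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher–Lee circular correlation between two angle sequences.

    Invariant to global offsets of either sequence; near +1 when one is a
    (forward) monotone reparametrization of the other.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    # pairwise form, O(n): sum_{i,j} sin(a_i-a_j) sin(b_i-b_j)
    num = 2 * ((sa @ sb) * (ca @ cb) - (sa @ cb) * (ca @ sb))
    den_a = n**2 - np.sum(np.cos(2 * a)) ** 2 - np.sum(np.sin(2 * a)) ** 2
    den_b = n**2 - np.sum(np.cos(2 * b)) ** 2 - np.sum(np.sin(2 * b)) ** 2
    denom = np.sqrt(den_a * den_b)
    if denom == 0:
        return 0.0
    return float(2 * num / denom)
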