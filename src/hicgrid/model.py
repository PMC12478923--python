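"""Deep tensor-factorization imputation of contact-map grids.

The model learns embedding tables for biosamples, assays, genomic positions
and pairwise bin distances.  A query (biosample b, assay a, bins i, j) is
canonicalised to i <= j (which makes the prediction exactly symmetric in the
two positions), the five embedding rows are concatenated and passed through
a multilayer perceptron with rectified-linear hidden layers and dropout, and
the scalar output regresses the normalized log contact value.  Training
minimises mean squared error with Adam over batches of randomly sampled
off-diagonal entries of the training maps; after every epoch the full
validation MSE is computed and the parameters from the best validation epoch
are kept.

An optional convolutional position encoder replaces each raw position row by
a learned linear combination of the 21 position rows centred on it (10
either side, zero rows beyond the chromosome ends) before concatenation.

The public surface is statsmodels-shaped: :class:`ContactGridModel` holds
data plus hyperparameters, its :meth:`~ContactGridModel.fit` returns a
:class:`ContactGridResults` carrying the fitted state, training history and
prediction methods.  The module-level functions (:func:`init_state`,
:func:`forward`, :func:`sample_batch`, :func:`train`, :func:`predict_map`)
expose the same machinery functionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import BinnedContactMap, ExperimentGrid, ExperimentKey, GridValidationError
from .preprocess import SplitAssignment

__all__ = [
    "Hyperparams",
    "ModelState",
    "ContactGridModel",
    "ContactGridResults",
    "init_state",
    "forward",
    "sample_batch",
    "train",
    "predict_map",
]

_DTYPE = np.float32
_EVAL_CHUNK = 16384


@dataclass(frozen=True)
class Hyperparams:
    """Model and training hyperparameters.

    Defaults are the best configuration found by random search at 100 kb
    resolution: 16 biosample factors, 128 assay/position/distance factors,
    4 hidden layers of 256 rectified-linear units, dropout 0.4, Adam with
    initial learning rate 1e-4, batches of 10,000 examples, 526 batches per
    epoch, at most 50 epochs.
    """

    learning_rate: float = 1e-4
    dropout: float = 0.4
    n_biosample_factors: int = 16
    n_assay_factors: int = 128
    n_position_factors: int = 128
    n_distance_factors: int = 128
    n_layers: int = 4
    n_nodes: int = 256
    epochs: int = 50
    batch_size: int = 10000
    batches_per_epoch: int = 526

    def __post_init__(self) -> None:
        for name in ("learning_rate", "n_biosample_factors", "n_assay_factors",
                     "n_position_factors", "n_distance_factors", "n_layers",
                     "n_nodes", "epochs", "batch_size", "batches_per_epoch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def input_dim(self) -> int:
        return (self.n_biosample_factors + self.n_assay_factors
                + 2 * self.n_position_factors + self.n_distance_factors)


@dataclass
class ModelState:
    """All learned parameters plus bookkeeping for one fitted (or fresh) model.

    ``params`` maps parameter names to float32 arrays: the four embedding
    tables (``emb_biosample``, ``emb_assay``, ``emb_position``,
    ``emb_distance`` — the distance table has one row per possible bin
    separation 0..n_bins-1), the MLP weights ``W0..W{L-1}``/``b0..`` and
    output layer ``W_out``/``b_out``, plus the convolutional encoder weights
    when ``conv_window`` is set.
    """

    hp: Hyperparams
    biosamples: list[str]
    assays: list[str]
    n_bins: int
    seed: int
    params: dict[str, np.ndarray]
    conv_window: int | None = None
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"train_loss": [], "validation_mse": []})
    best_epoch: int = -1

    @property
    def n_biosamples(self) -> int:
        return len(self.biosamples)

    @property
    def n_assays(self) -> int:
        return len(self.assays)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def save(self, path: str) -> None:
        """Single-file checkpoint (NumPy archive with a JSON metadata entry)."""
        meta = {
            "schema_version": 1,
            "hyperparams": asdict(self.hp),
            "biosamples": self.biosamples,
            "assays": self.assays,
            "n_bins": self.n_bins,
            "seed": self.seed,
            "conv_window": self.conv_window,
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        np.savez(path, _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str) -> "ModelState":
        with np.load(path) as npz:
            meta = json.loads(npz["_meta"].tobytes().decode())
            params = {k: npz[k] for k in npz.files if k != "_meta"}
        return cls(hp=Hyperparams(**meta["hyperparams"]),
                   biosamples=meta["biosamples"], assays=meta["assays"],
                   n_bins=meta["n_bins"], seed=meta["seed"], params=params,
                   conv_window=meta["conv_window"], history=meta["history"],
                   best_epoch=meta["best_epoch"])


def init_state(hp: Hyperparams, n_biosamples: int, n_assays: int, n_bins: int,
               seed: int, conv_window: int | None = None,
               biosamples: list[str] | None = None,
               assays: list[str] | None = None) -> ModelState:
    """Fresh model state with seeded random initialization.

    Embedding rows are standard normal; linear layers use the conventional
    uniform fan-in initialization.  Deterministic given ``seed``.
    """
    if min(n_biosamples, n_assays, n_bins) <= 0:
        raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    p: dict[str, np.ndarray] = {}
    p["emb_biosample"] = rng.standard_normal(
        (n_biosamples, hp.n_biosample_factors)).astype(_DTYPE)
    p["emb_assay"] = rng.standard_normal(
        (n_assays, hp.n_assay_factors)).astype(_DTYPE)
    p["emb_position"] = rng.standard_normal(
        (n_bins, hp.n_position_factors)).astype(_DTYPE)
    p["emb_distance"] = rng.standard_normal(
        (n_bins, hp.n_distance_factors)).astype(_DTYPE)

    def linear(fan_in: int, fan_out: int, name: str) -> None:
        bound = 1.0 / np.sqrt(fan_in)
        p[f"W{name}"] = rng.uniform(-bound, bound,
                                    (fan_in, fan_out)).astype(_DTYPE)
        p[f"b{name}"] = rng.uniform(-bound, bound, fan_out).astype(_DTYPE)

    linear(hp.input_dim, hp.n_nodes, "0")
    for layer in range(1, hp.n_layers):
        linear(hp.n_nodes, hp.n_nodes, str(layer))
    linear(hp.n_nodes, 1, "_out")

    if conv_window is not None:
        width = 2 * conv_window + 1
        bound1 = 1.0 / np.sqrt(width)
        p["conv1_w"] = rng.uniform(-bound1, bound1, (3, width)).astype(_DTYPE)
        p["conv1_b"] = rng.uniform(-bound1, bound1, 3).astype(_DTYPE)
        bound2 = 1.0 / np.sqrt(3)
        p["conv2_w"] = rng.uniform(-bound2, bound2, 3).astype(_DTYPE)
        p["conv2_b"] = rng.uniform(-bound2, bound2, 1).astype(_DTYPE)

    return ModelState(hp=hp,
                      biosamples=list(biosamples) if biosamples is not None
                      else [f"biosample{k}" for k in range(n_biosamples)],
                      assays=list(assays) if assays is not None
                      else [f"assay{k}" for k in range(n_assays)],
                      n_bins=n_bins, seed=seed, params=p,
                      conv_window=conv_window)


def _canonicalize(i: np.ndarray, j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    return np.minimum(i, j), np.maximum(i, j)


def _position_vectors(state: ModelState, pos: np.ndarray,
                      cache: dict | None = None) -> np.ndarray:
    """Raw or convolution-encoded position vectors for bin indices ``pos``."""
    emb = state.params["emb_position"]
    if state.conv_window is None:
        return emb[pos]
    w = state.conv_window
    width = 2 * w + 1
    padded = np.zeros((state.n_bins + 2 * w, emb.shape[1]), dtype=emb.dtype)
    padded[w:w + state.n_bins] = emb
    # windows exiting the chromosome see the zero rows of the padding
    windows = np.stack([padded[pos + off] for off in range(width)], axis=1)
    k = state.params["conv2_w"] @ state.params["conv1_w"]        # (width,)
    beta = float(state.params["conv2_w"] @ state.params["conv1_b"]
                 + state.params["conv2_b"][0])
    out = np.einsum("bwf,w->bf", windows, k.astype(emb.dtype)) + beta
    if cache is not None:
        cache["windows"] = windows
        cache["kernel"] = k
    return out


def _mlp_forward(state: ModelState, x: np.ndarray, training: bool,
                 rng: np.random.Generator | None,
                 cache: dict | None = None) -> np.ndarray:
    hp = state.hp
    p = state.params
    h = x
    hiddens, masks = [], []
    for layer in range(hp.n_layers):
        z = h @ p[f"W{layer}"] + p[f"b{layer}"]
        h = np.maximum(z, 0)
        if training and hp.dropout > 0:
            mask = (rng.random(h.shape) >= hp.dropout).astype(h.dtype)
            h = h * mask / (1.0 - hp.dropout)
            masks.append(mask)
        hiddens.append(h)
    y = (h @ p["W_out"] + p["b_out"])[:, 0]
    if cache is not None:
        cache["x"], cache["hiddens"], cache["masks"] = x, hiddens, masks
    return y


def forward(state: ModelState, b: np.ndarray, a: np.ndarray,
            i: np.ndarray, j: np.ndarray, training: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Predicted values for queries ``(b, a, i, j)`` (vectorised).

    Queries are canonicalised to ``min(i,j), max(i,j)`` before embedding
    lookup, so ``forward(b,a,i,j) == forward(b,a,j,i)`` exactly.  Dropout is
    active only with ``training=True`` (which then requires ``rng``).
    In evaluation mode the computation is deterministic.
    """
    b = np.asarray(b, dtype=np.int64)
    a = np.asarray(a, dtype=np.int64)
    i, j = _canonicalize(i, j)
    for idx, n in ((b, state.n_biosamples), (a, state.n_assays),
                   (i, state.n_bins), (j, state.n_bins)):
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise IndexError("query index out of range")
    p = state.params
    x = np.concatenate([
        p["emb_biosample"][b], p["emb_assay"][a],
        _position_vectors(state, i), _position_vectors(state, j),
        p["emb_distance"][j - i]], axis=1)
    return _mlp_forward(state, x, training, rng)


def _forward_backward(state: ModelState, b, a, i, j, targets,
                      rng: np.random.Generator) -> tuple[float, dict]:
    """Training-mode forward pass plus gradients of the batch MSE."""
    hp, p = state.hp, state.params
    i, j = _canonicalize(i, j)
    cache_i: dict = {}
    cache_j: dict = {}
    pos_i = _position_vectors(state, i, cache_i)
    pos_j = _position_vectors(state, j, cache_j)
    x = np.concatenate([p["emb_biosample"][b], p["emb_assay"][a],
                        pos_i, pos_j, p["emb_distance"][j - i]], axis=1)
    mlp_cache: dict = {}
    y = _mlp_forward(state, x, True, rng, mlp_cache)
    resid = y - targets.astype(y.dtype)
    loss = float(np.mean(resid ** 2))

    grads: dict[str, np.ndarray] = {}
    dy = (2.0 / resid.size) * resid
    h_last = mlp_cache["hiddens"][-1]
    grads["W_out"] = h_last.T @ dy[:, None]
    grads["b_out"] = np.array([dy.sum()], dtype=_DTYPE)
    dh = dy[:, None] @ p["W_out"].T
    for layer in range(hp.n_layers - 1, -1, -1):
        h = mlp_cache["hiddens"][layer]
        if hp.dropout > 0:
            dh = dh * mlp_cache["masks"][layer] / (1.0 - hp.dropout)
        dz = dh * (h > 0)
        h_prev = mlp_cache["hiddens"][layer - 1] if layer else mlp_cache["x"]
        grads[f"W{layer}"] = h_prev.T @ dz
        grads[f"b{layer}"] = dz.sum(axis=0)
        dh = dz @ p[f"W{layer}"].T
    dx = dh

    f_b, f_a = hp.n_biosample_factors, hp.n_assay_factors
    f_p, f_d = hp.n_position_factors, hp.n_distance_factors
    ofs = np.cumsum([f_b, f_a, f_p, f_p])
    d_eb, d_ea, d_pi, d_pj, d_ed = np.split(dx, ofs, axis=1)

    grads["emb_biosample"] = np.zeros_like(p["emb_biosample"])
    np.add.at(grads["emb_biosample"], b, d_eb)
    grads["emb_assay"] = np.zeros_like(p["emb_assay"])
    np.add.at(grads["emb_assay"], a, d_ea)
    grads["emb_distance"] = np.zeros_like(p["emb_distance"])
    np.add.at(grads["emb_distance"], j - i, d_ed)

    grads["emb_position"] = np.zeros_like(p["emb_position"])
    if state.conv_window is None:
        np.add.at(grads["emb_position"], i, d_pi)
        np.add.at(grads["emb_position"], j, d_pj)
    else:
        w = state.conv_window
        width = 2 * w + 1
        k = cache_i["kernel"]
        dk = np.zeros_like(k)
        dbeta = 0.0
        for pos, dv, cache in ((i, d_pi, cache_i), (j, d_pj, cache_j)):
            dk += np.einsum("bf,bwf->w", dv, cache["windows"],
                            dtype=np.float64).astype(k.dtype)
            dbeta += float(dv.sum())
            for off in range(width):
                tgt = pos + off - w
                ok = (tgt >= 0) & (tgt < state.n_bins)
                np.add.at(grads["emb_position"], tgt[ok],
                          dv[ok] * k[off])
        grads["conv1_w"] = p["conv2_w"][:, None] * dk[None, :]
        grads["conv2_w"] = (p["conv1_w"] @ dk
                            + p["conv1_b"] * dbeta).astype(_DTYPE)
        grads["conv1_b"] = (p["conv2_w"] * dbeta).astype(_DTYPE)
        grads["conv2_b"] = np.array([dbeta], dtype=_DTYPE)
    return loss, grads


class _Adam:
    """Adam with the conventional beta/epsilon defaults."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype, copy=False)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= (self.lr * (self.m[k] / corr1)
                          / (np.sqrt(self.v[k] / corr2) + self.eps))


def _index_maps(state: ModelState) -> tuple[dict[str, int], dict[str, int]]:
    return ({b: k for k, b in enumerate(state.biosamples)},
            {a: k for k, a in enumerate(state.assays)})


def _grid_examples(grid: ExperimentGrid, keys: list[ExperimentKey],
                   state: ModelState) -> list[tuple[int, int, np.ndarray]]:
    bidx, aidx = _index_maps(state)
    out = []
    for key in keys:
        if key not in grid.maps:
            continue
        out.append((bidx[key.biosample], aidx[key.assay],
                    grid.maps[key].values))
    return out


def sample_batch(train_maps: list[tuple[int, int, np.ndarray]],
                 batch_size: int, rng: np.random.Generator,
                 triu: tuple[np.ndarray, np.ndarray] | None = None):
    """Uniform-with-replacement sample of off-diagonal training entries.

    ``train_maps`` holds ``(biosample_index, assay_index, values)`` triples.
    Each example is an (experiment, unordered off-diagonal pair) drawn
    uniformly; pairs are returned canonicalised with ``i < j``.
    """
    if not train_maps:
        raise GridValidationError("no training maps to sample from")
    n = train_maps[0][2].shape[0]
    if triu is None:
        triu = np.triu_indices(n, k=1)
    iu, ju = triu
    exp = rng.integers(0, len(train_maps), size=batch_size)
    pair = rng.integers(0, iu.size, size=batch_size)
    i, j = iu[pair], ju[pair]
    b = np.empty(batch_size, dtype=np.int64)
    a = np.empty(batch_size, dtype=np.int64)
    t = np.empty(batch_size, dtype=np.float64)
    for e, (bi, ai, vals) in enumerate(train_maps):
        sel = exp == e
        b[sel], a[sel] = bi, ai
        t[sel] = vals[i[sel], j[sel]]
    return b, a, i, j, t


def _validation_mse(state: ModelState,
                    val_maps: list[tuple[int, int, np.ndarray]],
                    include_diagonal: bool = False) -> float:
    """Pooled MSE over the (off-diagonal) upper triangle of every map."""
    n = state.n_bins
    iu, ju = np.triu_indices(n, k=0 if include_diagonal else 1)
    total, count = 0.0, 0
    for bi, ai, vals in val_maps:
        targets = vals[iu, ju]
        for start in range(0, iu.size, _EVAL_CHUNK):
            sl = slice(start, start + _EVAL_CHUNK)
            pred = forward(state, np.full(iu[sl].size, bi),
                           np.full(iu[sl].size, ai), iu[sl], ju[sl])
            total += float(np.sum((pred - targets[sl]) ** 2))
            count += iu[sl].size
    if count == 0:
        raise GridValidationError("no validation entries")
    return total / count


def train(grid: ExperimentGrid, split: SplitAssignment, hp: Hyperparams,
          seed: int, conv_window: int | None = None,
          verbose: bool = False) -> ModelState:
    """Fit the factorization model on the training experiments of ``grid``.

    Minimises batch MSE with Adam; computes the full validation MSE after
    every epoch and returns the parameter snapshot from the epoch with the
    lowest validation MSE.  ``history`` records every epoch.  Deterministic
    given ``seed`` (single seeded generator drives initialization, batch
    sampling and dropout).
    """
    train_keys = sorted(split.keys_for("train"))
    val_keys = sorted(split.keys_for("validation"))
    if not any(k in grid.maps for k in val_keys):
        raise GridValidationError("split has no validation experiments")
    state = init_state(hp, len(grid.biosamples), len(grid.assays),
                       next(iter(grid.maps.values())).n_bins, seed,
                       conv_window=conv_window,
                       biosamples=grid.biosamples, assays=grid.assays)
    train_maps = _grid_examples(grid, train_keys, state)
    val_maps = _grid_examples(grid, val_keys, state)
    if not train_maps:
        raise GridValidationError("split has no training experiments")

    rng = np.random.default_rng(seed)
    opt = _Adam(state.params, hp.learning_rate)
    triu = np.triu_indices(state.n_bins, k=1)
    best_mse = np.inf
    best_params = state.copy_params()
    for epoch in range(hp.epochs):
        losses = 0.0
        for _ in range(hp.batches_per_epoch):
            b, a, i, j, t = sample_batch(train_maps, hp.batch_size, rng, triu)
            loss, grads = _forward_backward(state, b, a, i, j, t, rng)
            opt.step(state.params, grads)
            losses += loss
        val_mse = _validation_mse(state, val_maps)
        state.history["train_loss"].append(losses / hp.batches_per_epoch)
        state.history["validation_mse"].append(val_mse)
        if val_mse < best_mse:
            best_mse = val_mse
            best_params = state.copy_params()
            state.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:3d}  train {losses / hp.batches_per_epoch:.5f}"
                  f"  validation {val_mse:.5f}")
    state.params = best_params
    return state


def predict_map(state: ModelState, biosample: str, assay: str,
                template: BinnedContactMap) -> BinnedContactMap:
    """Whole-map prediction for one (biosample, assay) cell.

    All pairs i <= j are predicted in evaluation mode and reflected across
    the diagonal, so the output is exactly symmetric.  Diagonal entries are
    model outputs at distance 0, an extrapolation: training never samples
    the diagonal.
    """
    bidx, aidx = _index_maps(state)
    if biosample not in bidx:
        raise KeyError(f"unknown biosample {biosample!r}")
    if assay not in aidx:
        raise KeyError(f"unknown assay {assay!r}")
    n = state.n_bins
    iu, ju = np.triu_indices(n)
    pred = np.empty(iu.size, dtype=np.float64)
    for start in range(0, iu.size, _EVAL_CHUNK):
        sl = slice(start, start + _EVAL_CHUNK)
        pred[sl] = forward(state, np.full(iu[sl].size, bidx[biosample]),
                           np.full(iu[sl].size, aidx[assay]), iu[sl], ju[sl])
    out = np.zeros((n, n))
    out[iu, ju] = pred
    out[ju, iu] = pred
    # predictions may be slightly negative; contact maps are non-negative
    np.clip(out, 0, None, out=out)
    return template.with_values(out)


class ContactGridModel:
    """Factorization imputation model over a preprocessed experiment grid.

    Parameters
    ----------
    grid : ExperimentGrid
        Preprocessed (log-transformed, pruned, sum-normalized) grid.
    split : SplitAssignment
        Train/validation/test labels; training uses the train maps, model
        selection the validation maps.
    hyperparams : Hyperparams, optional
        Defaults to the best searched configuration.
    conv_window : int, optional
        Half-width of the convolutional position encoder window (10 gives
        the 21-position window); ``None`` uses raw position embeddings.
    """

    def __init__(self, grid: ExperimentGrid, split: SplitAssignment,
                 hyperparams: Hyperparams | None = None,
                 conv_window: int | None = None):
        self.grid = grid
        self.split = split
        self.hyperparams = hyperparams or Hyperparams()
        self.conv_window = conv_window

    def fit(self, seed: int = 0, verbose: bool = False) -> "ContactGridResults":
        state = train(self.grid, self.split, self.hyperparams, seed,
                      conv_window=self.conv_window, verbose=verbose)
        return ContactGridResults(self, state)


class ContactGridResults:
    """Fitted model: parameters, training history, prediction and summary."""

    def __init__(self, model: ContactGridModel, state: ModelState):
        self.model = model
        self.state = state
        self._template = next(iter(model.grid.maps.values()))

    @property
    def history(self):
        import pandas as pd
        return pd.DataFrame(self.state.history)

    @property
    def best_epoch(self) -> int:
        return self.state.best_epoch

    @property
    def best_validation_mse(self) -> float:
        return float(min(self.state.history["validation_mse"]))

    def predict_map(self, biosample: str, assay: str) -> BinnedContactMap:
        return predict_map(self.state, biosample, assay, self._template)

    def impute_missing(self) -> ExperimentGrid:
        """Complete grid: observed maps kept, missing cells imputed."""
        grid = self.model.grid
        maps = dict(grid.maps)
        for key in grid.missing_keys:
            maps[key] = self.predict_map(key.biosample, key.assay)
        return ExperimentGrid(biosamples=list(grid.biosamples),
                              assays=list(grid.assays), maps=maps)

    def save(self, path: str) -> None:
        self.state.save(path)

    def summary(self) -> str:
        hp = self.state.hp
        lines = [
            "Contact-grid factorization imputation results",
            "=" * 53,
            f"biosamples: {self.state.n_biosamples:>5d}    "
            f"assays: {self.state.n_assays:>5d}    bins: {self.state.n_bins}",
            f"factors (biosample/assay/position/distance): "
            f"{hp.n_biosample_factors}/{hp.n_assay_factors}/"
            f"{hp.n_position_factors}/{hp.n_distance_factors}",
            f"MLP: {hp.n_layers} x {hp.n_nodes} ReLU, dropout {hp.dropout}",
            f"optimizer: Adam, lr {hp.learning_rate:g}, "
            f"batch {hp.batch_size}, {hp.batches_per_epoch} batches/epoch",
            f"position encoder: "
            + (f"conv, window {2 * self.state.conv_window + 1}"
               if self.state.conv_window is not None else "embedding lookup"),
            "-" * 53,
            f"epochs trained:        {len(self.state.history['train_loss'])}",
            f"best epoch:            {self.state.best_epoch}",
            f"best validation MSE:   {self.best_validation_mse:.6f}",
            f"final train loss:      {self.state.history['train_loss'][-1]:.6f}",
            "=" * 53,
        ]
        return "\n".join(lines)
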