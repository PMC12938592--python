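"""Recurrent estimator of adaptation level from gait-variability windows.

An LSTM (128 hidden units, linear head) consumes the chronological
sequence of 3-feature variability windows — step-frequency, MHF-angle and
MHE-angle variances — and emits one adaptation-level estimate per window
(i.e. every 10 strides).  The recurrent state is carried across a
subject's entire chronological sequence, across blocks and days, and
reset only between subjects: the features carry no explicit clock, so
accumulated history is the only way the model can track exposure.

Training minimizes mean-squared error against the metabolic ground-truth
labels with Adam, with early stopping on a held-out chronological tail of
each training subject's sequence (a random window split would leak the
temporal structure the model is supposed to learn).  Inference is causal
and the output is clipped to [0, 100]%.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from ._lstm import Adam, LSTMRegressor, clip_gradients

__all__ = [
    "EstimatorConfig",
    "FeatureScaler",
    "SubjectSequence",
    "TrainedEstimator",
    "fit_scaler",
    "train",
    "predict_stream",
]

log = logging.getLogger(__name__)

N_FEATURES = 3
LABEL_SCALE = 100.0  # network trains on labels / 100


@dataclass(frozen=True)
class EstimatorConfig:
    hidden_units: int = 128
    num_layers: int = 1
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20  # epochs without validation improvement
    val_fraction: float = 0.2
    grad_clip: float = 1.0
    seed: int = 0
    log_features: bool = True  # log-transform variances before scaling
    # Training-time augmentations (both derive from config.seed).
    # Level offsets: a per-epoch random constant (log-variance units) added
    # to each training sequence, enforcing invariance to subject-specific
    # variance levels so the model keys on the decay *shape*.
    augment_level_sd: float = 0.3
    # Time warp: each epoch resamples every training sequence by a random
    # rate factor exp(N(0, sd)) with the labels warped consistently,
    # broadening the range of adaptation time constants seen in training
    # beyond the handful of real training subjects.
    augment_time_log_sd: float = 0.0
    # Parametric-bootstrap virtual subjects: fit the exponential decay
    # family to the *training* subjects, then simulate extra training
    # sequences from the fitted family (exact chi-square window sampling
    # noise).  Turns the handful of real sequences into dense coverage of
    # the time-constant range, so the network learns the decay-rate ->
    # adaptation mapping instead of memorizing the training subjects.
    # 0 disables.
    n_virtual_subjects: int = 0
    virtual_tau_extra_log_sd: float = 0.35  # widens the fitted tau spread
    virtual_level_jitter: float = 0.3  # lognormal jitter on v0/vss
    # 0: draw the virtual subjects once per training run; k > 0: redraw
    # them every k epochs (a slowly moving objective)
    virtual_redraw_every: int = 0
    # train on virtual subjects only (pure simulation-based inference);
    # the real training subjects then contribute the decay-family fit and
    # the validation tails, but never appear in the training loss
    virtual_only: bool = False
    # model selection: "tail" scores only the held-out chronological tails,
    # "full" scores the real subjects' entire clean sequences (the tails
    # still never enter the training loss)
    select_on: str = "tail"
    # validation (on un-augmented sequences) is evaluated every N epochs
    val_every: int = 5
    # learning rate is multiplied by 0.5 at these fractions of max_epochs
    lr_decay_at: tuple[float, ...] = (0.6, 0.85)
    # exponential moving average of the weights; averages out the noise the
    # stochastic augmentation injects into individual epochs.  0 (default)
    # disables it and the best-validation-loss weights are returned.
    # Tracking starts at ema_start_frac of max_epochs so early undertrained
    # weights never enter the average.
    ema_decay: float = 0.0
    ema_start_frac: float = 0.6

    def __post_init__(self) -> None:
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if not (0.0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must lie in (0, 0.5)")


@dataclass
class SubjectSequence:
    """One subject's chronological window features and labels.

    ``exposures`` (cumulative with-suit minutes per window) is optional;
    when absent, a uniform grid over 240 min is assumed.  It is only used
    to anchor virtual training subjects in time, never as a model input.
    """

    subject_id: str
    features: np.ndarray  # (n_windows, 3)
    labels: np.ndarray  # (n_windows,), adaptation level in [0, 100]
    exposures: np.ndarray | None = None  # (n_windows,), min

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != N_FEATURES:
            raise ValueError(f"features must be (n, {N_FEATURES})")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels and features must align")
        if self.exposures is not None:
            self.exposures = np.asarray(self.exposures, dtype=float)
            if self.exposures.shape != self.labels.shape:
                raise ValueError("exposures and labels must align")

    @property
    def exposure_grid(self) -> np.ndarray:
        if self.exposures is not None:
            return self.exposures
        n = self.labels.shape[0]
        return np.arange(n) * (240.0 / max(n, 1))


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on training subjects only.

    Variances are heavy-tailed and span orders of magnitude across the
    three features, so a log transform (with a small floor for exact
    zeros) precedes the z-score.  A constant feature gets sd forced to 1
    and is flagged.
    """

    mean: np.ndarray
    sd: np.ndarray
    log_transform: bool = True
    constant_features: list[int] = field(default_factory=list)

    _LOG_FLOOR = 1e-12

    def _pre(self, X: np.ndarray) -> np.ndarray:
        if not self.log_transform:
            return X
        return np.log(np.maximum(X, 0.0) + self._LOG_FLOOR)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (self._pre(np.asarray(X, dtype=float)) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "log_transform": self.log_transform,
            "constant_features": self.constant_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            log_transform=bool(d["log_transform"]),
            constant_features=list(d["constant_features"]),
        )


def fit_scaler(
    train_features: np.ndarray, log_transform: bool = True
) -> FeatureScaler:
    """Zero-mean/unit-variance scaler from training windows only."""
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training windows")
    scaler = FeatureScaler(
        mean=np.zeros(X.shape[1]), sd=np.ones(X.shape[1]), log_transform=log_transform
    )
    Z = scaler._pre(X)
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    constant = [int(i) for i in np.flatnonzero(sd == 0.0)]
    if constant:
        warnings.warn(f"constant feature(s) {constant}: sd forced to 1")
        sd = sd.copy()
        sd[constant] = 1.0
    scaler.mean, scaler.sd, scaler.constant_features = mean, sd, constant
    return scaler


@dataclass
class TrainedEstimator:
    model: LSTMRegressor
    scaler: FeatureScaler
    config: EstimatorConfig
    history: dict = field(default_factory=dict)  # train/val loss per epoch
    best_epoch: int = -1

    def save(self, path) -> None:
        """Checkpoint: config + scaler as JSON inside an npz of weights."""
        meta = {
            "config": asdict(self.config),
            "scaler": self.scaler.to_dict(),
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        np.savez(
            path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.model.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "TrainedEstimator":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["config"]["lr_decay_at"] = tuple(meta["config"]["lr_decay_at"])
        config = EstimatorConfig(**meta["config"])
        model = LSTMRegressor(
            N_FEATURES,
            hidden=config.hidden_units,
            num_layers=config.num_layers,
            seed=config.seed,
        )
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return cls(
            model=model,
            scaler=FeatureScaler.from_dict(meta["scaler"]),
            config=config,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
        )


def _pack_sequences(
    sequences: list[SubjectSequence], scaler: FeatureScaler, val_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pad subjects to a common length -> (X, Y, train_mask, val_mask).

    The validation mask covers the chronological tail (``val_fraction``)
    of each subject's sequence; padded steps belong to neither mask.
    """
    T = max(s.features.shape[0] for s in sequences)
    B = len(sequences)
    X = np.zeros((T, B, N_FEATURES), dtype=np.float32)
    Y = np.zeros((T, B), dtype=np.float32)
    train_mask = np.zeros((T, B), dtype=np.float32)
    val_mask = np.zeros((T, B), dtype=np.float32)
    for b, seq in enumerate(sequences):
        n = seq.features.shape[0]
        X[:n, b] = scaler.transform(seq.features)
        Y[:n, b] = seq.labels / LABEL_SCALE
        n_val = max(1, int(round(val_fraction * n)))
        train_mask[: n - n_val, b] = 1.0
        val_mask[n - n_val : n, b] = 1.0
    return X, Y, train_mask, val_mask


def _augmented_batch(
    Xs: list[np.ndarray],
    Ys: list[np.ndarray],
    T: int,
    rng: np.random.Generator,
    warp_sd: float,
    level_sd: np.ndarray | None,
    val_fraction: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One epoch's augmented training batch (X, Y, train_mask).

    Each subject is resampled by a rate factor exp(N(0, warp_sd)) — a
    virtual subject whose adaptation time constant is scaled by the same
    factor, labels included — then shifted by a random per-sequence level
    offset.  The chronological validation tail stays excluded from the
    training mask.
    """
    B = len(Xs)
    X = np.zeros((T, B, N_FEATURES), dtype=np.float32)
    Y = np.zeros((T, B), dtype=np.float32)
    mask = np.zeros((T, B), dtype=np.float32)
    for b, (xb, yb) in enumerate(zip(Xs, Ys)):
        n = xb.shape[0]
        alpha = float(np.exp(rng.normal(0.0, warp_sd))) if warp_sd > 0 else 1.0
        pos = np.arange(T) / alpha
        valid = int(np.searchsorted(pos, n - 1, side="right"))
        idx = np.minimum(pos[:valid].astype(np.intp), n - 1)
        X[:valid, b] = xb[idx]
        Y[:valid, b] = yb[idx]
        mask[: max(1, int(valid * (1.0 - val_fraction))), b] = 1.0
    if level_sd is not None:
        X += (rng.normal(size=(1, B, N_FEATURES)) * level_sd).astype(np.float32)
    return X, Y, mask


def _fit_decay_family(seq: SubjectSequence) -> tuple[dict, float]:
    """Per-feature decay amplitudes and the label time constant.

    The label curve A(t) = 100 (1 - exp(-t/tau)) pins tau wherever the
    labels are away from their extremes.  The feature decays are then fit
    with tau *fixed* to that value: a free 3-parameter exponential is
    unidentifiable for subjects whose tau approaches the protocol length
    (it drifts to huge tau with a zero asymptote), whereas with tau fixed
    the amplitudes are a linear least-squares problem that stays well
    conditioned for any subject.
    """
    t = seq.exposure_grid
    A = seq.labels
    ok = (A > 5.0) & (A < 95.0) & (t > 0)
    if ok.sum() >= 3:
        tau_label = float(np.median(-t[ok] / np.log(1.0 - A[ok] / 100.0)))
    else:  # degenerate labels (constant): fall back to a nominal constant
        tau_label = 200.0
    tau_label = float(np.clip(tau_label, 5.0, 2000.0))
    basis = np.c_[np.ones_like(t), np.exp(-t / tau_label)]  # [vss, v0 - vss]
    feats: dict[int, tuple[float, float, float]] = {}
    for j in range(N_FEATURES):
        coef, *_ = np.linalg.lstsq(basis, seq.features[:, j], rcond=None)
        vss = max(float(coef[0]), 1e-13)
        v0 = max(float(coef[0] + coef[1]), vss * 1.01)
        feats[j] = (v0, vss, tau_label)
    return feats, tau_label


def _virtual_sequences(
    sequences: list[SubjectSequence],
    config: EstimatorConfig,
    rng: np.random.Generator,
) -> list[SubjectSequence]:
    """Parametric-bootstrap training subjects from the fitted decay family.

    A virtual subject borrows a real training subject's variance-decay
    shape, draws a new time constant from the (widened) fitted log-tau
    distribution and a label/feature time-constant ratio from the real
    subjects, jitters the variance levels, and emits window variances with
    the exact chi-square sampling noise of an n-window variance estimate.
    Only training-fold information enters.
    """
    fits, taus, ratios, log_mu, log_sd = _family_params(sequences, config)
    return _draw_virtual(
        sequences, fits, taus, ratios, log_mu, log_sd, config, rng
    )


def _family_params(
    sequences: list[SubjectSequence], config: EstimatorConfig
) -> tuple[list, np.ndarray, np.ndarray, float, float]:
    fits = [_fit_decay_family(s) for s in sequences]
    taus = np.array([np.mean([f[0][j][2] for j in f[0]]) for f in fits])
    ratios = np.array([f[1] / tv for f, tv in zip(fits, taus)])
    log_mu = float(np.mean(np.log(taus)))
    log_sd = float(np.std(np.log(taus)) + config.virtual_tau_extra_log_sd)
    return fits, taus, ratios, log_mu, log_sd


def _draw_virtual(
    sequences: list[SubjectSequence],
    fits: list,
    taus: np.ndarray,
    ratios: np.ndarray,
    log_mu: float,
    log_sd: float,
    config: EstimatorConfig,
    rng: np.random.Generator,
) -> list[SubjectSequence]:
    out: list[SubjectSequence] = []
    for v in range(config.n_virtual_subjects):
        base_idx = int(rng.integers(len(fits)))
        base = fits[base_idx]
        t = sequences[base_idx].exposure_grid
        tau_v = float(np.exp(rng.normal(log_mu, log_sd)))
        # label/feature time-constant mismatch: the adaptation curve and
        # the variability decay track each other only approximately
        rho = float(ratios[rng.integers(len(ratios))] * np.exp(rng.normal(0.0, 0.1)))
        X = np.empty((t.size, N_FEATURES))
        for j in range(N_FEATURES):
            v0, vss, _ = base[0][j]
            # a common level factor preserves the steady/initial variance
            # ratio (a population invariant the estimator relies on);
            # only a small independent jitter perturbs the ratio itself
            level = np.exp(rng.normal(0.0, config.virtual_level_jitter))
            v0 *= level
            vss *= level * np.exp(rng.normal(0.0, 0.1))
            mean_v = vss + (v0 - vss) * np.exp(-t / tau_v)
            # sample variance of 10 draws ~ v * chi2(9) / 9
            X[:, j] = mean_v * rng.chisquare(9, size=t.size) / 9.0
        labels = np.clip(
            100.0 * (1.0 - np.exp(-t / max(rho * tau_v, 1e-6))), 0.0, 100.0
        )
        out.append(
            SubjectSequence(f"virtual{v}", X, labels, exposures=t.copy())
        )
    return out


def train(
    sequences: list[SubjectSequence],
    config: EstimatorConfig | None = None,
    scaler: FeatureScaler | None = None,
) -> TrainedEstimator:
    """Train the LSTM on the given training subjects.

    All randomness (weight initialization) derives from ``config.seed``.
    Returns the weights of the epoch with the best validation loss; the
    per-epoch train/val loss history is recorded on the result.
    """
    config = config or EstimatorConfig()
    if not sequences:
        raise ValueError("need at least one training subject")
    for s in sequences:
        if s.features.shape[0] == 0:
            raise ValueError(f"subject {s.subject_id} has an empty sequence")
        if np.any(s.labels < 0) or np.any(s.labels > 100):
            raise ValueError("labels must lie in [0, 100]")
    family = None
    virt_rng = None
    if config.n_virtual_subjects > 0:
        # virtual subjects are redrawn fresh every epoch from the decay
        # family fitted to the real training subjects: effectively
        # unlimited simulated training data, so draw luck averages out
        # and the virtual family cannot be memorized
        family = _family_params(sequences, config)
        virt_rng = np.random.default_rng(
            np.random.SeedSequence(
                [config.seed, sum(ord(c) for s in sequences for c in s.subject_id)]
            )
        )
    if scaler is None:
        scaler = fit_scaler(
            np.concatenate([s.features for s in sequences]),
            log_transform=config.log_features,
        )
    Xc, Yc, train_mask, val_mask = _pack_sequences(
        sequences, scaler, config.val_fraction
    )
    if config.select_on == "full":
        val_mask = train_mask + val_mask
    elif config.select_on != "tail":
        raise ValueError("select_on must be 'tail' or 'full'")
    Xs = [scaler.transform(s.features).astype(np.float32) for s in sequences]
    Ys = [(s.labels / LABEL_SCALE).astype(np.float32) for s in sequences]
    T = Xc.shape[0]
    model = LSTMRegressor(
        N_FEATURES,
        hidden=config.hidden_units,
        num_layers=config.num_layers,
        seed=config.seed,
    )
    opt = Adam(lr=config.learning_rate)
    decay_epochs = {int(f * config.max_epochs) for f in config.lr_decay_at}
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    best_epoch = -1
    aug_rng = np.random.default_rng(config.seed + 1)
    augment = config.augment_level_sd > 0 or config.augment_time_log_sd > 0
    # level offsets act in log-variance space -> standardized units
    level_sd = (
        config.augment_level_sd / scaler.sd
        if (config.augment_level_sd > 0 and scaler.log_transform)
        else None
    )
    ema: list[np.ndarray] | None = None
    ema_start = int(config.ema_start_frac * config.max_epochs)
    Xs_virt: list[np.ndarray] = []
    Ys_virt: list[np.ndarray] = []
    for epoch in range(config.max_epochs):
        if epoch in decay_epochs:
            opt.lr *= 0.5
        if family is not None:
            redraw = (
                epoch == 0
                or (
                    config.virtual_redraw_every > 0
                    and epoch % config.virtual_redraw_every == 0
                )
            )
            if redraw:
                virt = _draw_virtual(sequences, *family, config, virt_rng)
                Xs_virt = [
                    scaler.transform(v.features).astype(np.float32) for v in virt
                ]
                Ys_virt = [
                    (v.labels / LABEL_SCALE).astype(np.float32) for v in virt
                ]
            if config.virtual_only:
                Xs_epoch, Ys_epoch = Xs_virt, Ys_virt
            else:
                Xs_epoch = Xs + Xs_virt
                Ys_epoch = Ys + Ys_virt
        else:
            Xs_epoch, Ys_epoch = Xs, Ys
        if augment or family is not None:
            X, Y, m_tr = _augmented_batch(
                Xs_epoch,
                Ys_epoch,
                T,
                aug_rng,
                config.augment_time_log_sd,
                level_sd,
                config.val_fraction,
            )
        else:
            X, Y, m_tr = Xc, Yc, train_mask
        out = model.forward(X)
        train_loss, dY = model.masked_mse(out, Y, m_tr)
        if not np.isfinite(train_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss={train_loss})"
            )
        history["train_loss"].append(train_loss)
        grads = model.backward(dY)
        clip_gradients(grads, config.grad_clip)
        opt.step(model.params, grads)
        if config.ema_decay > 0 and epoch >= ema_start:
            if ema is None:
                ema = [p.copy() for p in model.params]
            else:
                d = config.ema_decay
                for e, p in zip(ema, model.params):
                    e *= d
                    e += (1.0 - d) * p
        last = epoch == config.max_epochs - 1
        if epoch % config.val_every == config.val_every - 1 or last:
            # model selection and early stopping use the clean
            # (un-augmented) real sequences' chronological validation tails
            clean_batch = not augment and family is None
            val_out = out if clean_batch else model.forward(Xc)
            val_loss, _ = model.masked_mse(val_out, Yc, val_mask)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
                best_epoch = epoch
            elif epoch - best_epoch >= config.patience:
                log.debug("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
    if ema is not None:
        for p, e in zip(model.params, ema):
            p[...] = e
    elif best_state is not None:
        model.load_state_dict(best_state)
    return TrainedEstimator(
        model=model, scaler=scaler, config=config, history=history, best_epoch=best_epoch
    )


def predict_stream(
    estimator: TrainedEstimator, features: np.ndarray
) -> np.ndarray:
    """Causal per-window adaptation estimates (%) for one subject.

    ``features`` is the subject's full chronological (n_windows, 3) array
    of raw variances; scaling uses the training scaler.  The recurrent
    state runs across the whole sequence (it would be reset between
    subjects); estimate k uses windows 1..k only.  Output is clipped to
    [0, 100].
    """
    X = np.asarray(features, dtype=float)
    if X.size == 0:
        return np.empty(0)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"expected (n, {N_FEATURES}) features, got {X.shape}")
    Z = estimator.scaler.transform(X)[:, None, :]  # (T, 1, F)
    out = estimator.model.forward(Z)[:, 0] * LABEL_SCALE
    return np.clip(out, 0.0, 100.0)
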