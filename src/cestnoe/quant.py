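"""Training and prediction of the NOE(-1.6) amplitude/width regressors.

The regressor input is the pointwise ratio ``R1obs / Z`` restricted to
offsets in [-10, -0.8] U [5, 10] ppm: the inverse Z-spectrum linearizes the
inverse summation of saturation-transfer effects, dividing by nothing near
water avoids the direct-saturation singularity at 0 ppm, and downfield CEST
effects (other than fast amine exchange, whose broad tail reaches upfield)
carry no information about the upfield NOE peaks.

Amplitude and width are trained as separate scalar regressions.  Curriculum
learning repeats the training four times: the first pass sees clean inputs,
each later pass re-generates the inputs from the clean spectra with fresh
Gaussian noise (std 0.005) added to Z before input construction, teaching the
network to denoise.  Measured data has no clean version, so curriculum is
skipped there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import LorentzPeak, lorentz_peak
from .dataset import Sample, ZSpectrum, stack_samples
from .nn import CNNRegressor

__all__ = [
    "ModelConfig",
    "CurriculumConfig",
    "TrainedRegressor",
    "default_input_mask",
    "build_input",
    "split_train_val",
    "train_curriculum",
    "predict",
    "predict_spectra",
    "augment_pairwise",
    "pair_count",
    "fine_tune",
]

MASK_RANGES_PPM = ((-10.0, -0.8), (5.0, 10.0))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization settings of one regressor."""

    conv_filters: tuple[int, int, int] = (64, 32, 16)
    kernel_size: int = 3
    dropout_rate: float = 0.2
    dense_sizes: tuple[int, int] = (256, 128)
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs_first: int = 1000
    epochs_later: int = 100

    def __post_init__(self) -> None:
        a, b, c = self.conv_filters
        if not a > b > c:
            raise ValueError("conv filter counts must be strictly decreasing")
        if self.dense_sizes != (256, 128):
            raise ValueError("dense sizes are fixed at (256, 128)")


@dataclass(frozen=True)
class CurriculumConfig:
    """Denoising curriculum: total iterations and per-iteration noise."""

    n_iterations: int = 4
    noise_std: float = 0.005
    cumulative: bool = False  # if True: std grows as iteration * noise_std

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("need at least one training iteration")

    def iteration_std(self, iteration: int) -> float:
        """Noise std for 0-based iteration; the first pass is clean."""
        if iteration == 0:
            return 0.0
        return self.noise_std * (iteration if self.cumulative else 1.0)


def default_input_mask(grid) -> np.ndarray:
    """Boolean mask selecting offsets in [-10, -0.8] U [5, 10] ppm."""
    x = grid.offsets_ppm
    eps = 1e-9
    mask = np.zeros(x.shape, dtype=bool)
    for lo, hi in MASK_RANGES_PPM:
        mask |= (x >= lo - eps) & (x <= hi + eps)
    return mask


def build_input(zspec: ZSpectrum, mask: np.ndarray | None = None) -> np.ndarray:
    """``R1obs / Z`` at the masked offsets (s^-1)."""
    if mask is None:
        mask = default_input_mask(zspec.grid)
    z = zspec.z[mask]
    if np.any(z <= 0):
        raise ValueError("Z must be positive at every masked offset")
    return zspec.R1obs / z


def _input_matrix(z: np.ndarray, R1obs: np.ndarray, mask: np.ndarray) -> np.ndarray:
    zm = z[:, mask]
    if np.any(zm <= 0):
        raise ValueError("Z must be positive at every masked offset")
    return R1obs[:, None] / zm


def split_train_val(
    n: int, fractions: tuple[tuple[float, float], ...] = ((0.05, 0.10), (0.70, 0.80))
) -> tuple[np.ndarray, np.ndarray]:
    """Index split with validation in fixed non-contiguous index ranges.

    Validation covers [5%, 10%) and [70%, 80%) of the generation order
    (floor-based), probing both middle- and side-level parameter regions;
    training is the complement.
    """

    val = np.zeros(n, dtype=bool)
    for lo, hi in fractions:
        a, b = int(np.floor(lo * n)), int(np.floor(hi * n))
        if a >= b:
            raise ValueError(f"dataset of size {n} too small for a [{lo}, {hi}) split")
        val[a:b] = True
    idx = np.arange(n)
    return idx[~val], idx[val]


@dataclass
class TrainedRegressor:
    """A trained scalar regressor plus everything needed to apply it."""

    net: CNNRegressor
    target: str  # "A" or "W"
    mask_ppm: np.ndarray  # offsets the input covers, for compatibility checks
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    meta: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def copy(self) -> "TrainedRegressor":
        """Independent copy (safe to fine-tune without touching the original)."""
        return TrainedRegressor(
            net=self.net.copy(), target=self.target, mask_ppm=self.mask_ppm.copy(),
            x_mean=self.x_mean.copy(), x_std=self.x_std.copy(),
            y_mean=self.y_mean, y_std=self.y_std, meta=dict(self.meta),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(
            path / "weights.npz",
            **self.net.params,
            x_mean=self.x_mean,
            x_std=self.x_std,
            mask_ppm=self.mask_ppm,
        )
        meta = {
            "target": self.target,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "net": self.net.get_config(),
            "meta": self.meta,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedRegressor":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        blob = np.load(path / "weights.npz")
        net = CNNRegressor.from_config(meta["net"])
        for k in net.params:
            net.params[k][...] = blob[k]  # params are views into the flat buffer
        return cls(
            net=net,
            target=meta["target"],
            mask_ppm=blob["mask_ppm"],
            x_mean=blob["x_mean"],
            x_std=blob["x_std"],
            y_mean=meta["y_mean"],
            y_std=meta["y_std"],
            meta=meta["meta"],
        )


def train_curriculum(
    samples: list[Sample],
    model_cfg: ModelConfig = ModelConfig(),
    curriculum_cfg: CurriculumConfig = CurriculumConfig(),
    target: str = "A",
    seed: int = 0,
    use_curriculum: bool = True,
) -> TrainedRegressor:
    """Train one regressor with the denoising curriculum.

    ``use_curriculum=False`` (measured data, which has no clean version)
    runs only the first, noise-free iteration.
    """

    if target not in ("A", "W"):
        raise ValueError("target must be 'A' or 'W'")
    arrays = stack_samples(samples)
    mask = default_input_mask(samples[0].zspec.grid)
    mask_ppm = arrays["offsets_ppm"][mask]
    y_all = arrays["target_A"] if target == "A" else arrays["target_W"]
    n = len(samples)
    train_idx, val_idx = split_train_val(n)

    X_clean = _input_matrix(arrays["z"], arrays["R1obs"], mask)
    x_mean = X_clean[train_idx].mean(axis=0)
    x_std = X_clean[train_idx].std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_mean = float(y_all[train_idx].mean())
    y_std = float(y_all[train_idx].std()) or 1.0

    net = CNNRegressor(
        input_len=int(mask.sum()),
        conv_filters=model_cfg.conv_filters,
        kernel=model_cfg.kernel_size,
        dropout=model_cfg.dropout_rate,
        dense=model_cfg.dense_sizes,
        seed=seed,
    )
    model = TrainedRegressor(
        net=net, target=target, mask_ppm=mask_ppm,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
    )
    y_scaled = (y_all - y_mean) / y_std

    n_iters = curriculum_cfg.n_iterations if use_curriculum else 1
    rng = np.random.default_rng(seed)
    losses = []
    optimizer = None
    for it in range(n_iters):
        std = curriculum_cfg.iteration_std(it)
        if std > 0:
            z_noisy = arrays["z"] + rng.normal(0.0, std, size=arrays["z"].shape)
            X = _input_matrix(np.clip(z_noisy, 1e-4, None), arrays["R1obs"], mask)
        else:
            X = X_clean
        Xs = model.transform(X)
        epochs = model_cfg.epochs_first if it == 0 else model_cfg.epochs_later
        try:
            hist = net.fit(
                Xs[train_idx], y_scaled[train_idx],
                epochs=epochs,
                batch_size=model_cfg.batch_size,
                lr=model_cfg.learning_rate,
                seed=int(rng.integers(2**31)),
                X_val=Xs[val_idx], y_val=y_scaled[val_idx],
                optimizer=optimizer,
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"training diverged in curriculum iteration {it}") from exc
        optimizer = hist.pop("optimizer")
        losses.append({"iteration": it, "noise_std": std, **{k: v[-1] for k, v in hist.items() if v}})
    model.meta = {
        "seed": seed,
        "target": target,
        "n_samples": n,
        "curriculum": use_curriculum,
        "iterations": losses,
    }
    return model


def predict(model: TrainedRegressor, zspecs: list) -> np.ndarray:
    """Per-spectrum scalar predictions (A in s^-1 or W in ppm).

    Accepts a list of :class:`ZSpectrum` or :class:`Sample` objects.
    """
    if not zspecs:
        return np.empty(0)
    specs = [z.zspec if isinstance(z, Sample) else z for z in zspecs]
    mask = default_input_mask(specs[0].grid)
    if int(mask.sum()) != model.net.input_len:
        raise ValueError(
            f"input length {int(mask.sum())} does not match the trained mask "
            f"({model.net.input_len})"
        )
    X = np.stack([build_input(z, mask) for z in specs])
    pred = model.net.predict(model.transform(X).astype(np.float32))
    return pred.astype(float) * model.y_std + model.y_mean


def predict_spectra(A: np.ndarray, W: np.ndarray, offsets_ppm: np.ndarray) -> np.ndarray:
    """Regenerated NOE(-1.6) peaks A/(1+(dw+1.6)^2/(0.5W)^2), one row per sample."""
    out = np.empty((len(A), len(offsets_ppm)))
    for i, (a, w) in enumerate(zip(A, W)):
        out[i] = lorentz_peak(LorentzPeak(A=max(a, 0.0), W=max(w, 1e-6), delta_ppm=-1.6), offsets_ppm)
    return out


def pair_count(n: int) -> int:
    """Number of unordered pairs n(n-1)/2 produced by pairwise averaging."""
    return n * (n - 1) // 2


def augment_pairwise(zspecs: list[ZSpectrum]) -> list[ZSpectrum]:
    """Average every unordered pair of spectra (z, R1obs and fm averaged).

    Grows a measured dataset by a factor ~n/2; training targets for the
    augmented spectra must be re-derived (Lorentzian fit of the averages).
    """

    out: list[ZSpectrum] = []
    for i in range(len(zspecs)):
        for j in range(i + 1, len(zspecs)):
            a, b = zspecs[i], zspecs[j]
            out.append(
                ZSpectrum(
                    grid=a.grid,
                    z=0.5 * (a.z + b.z),
                    R1obs=0.5 * (a.R1obs + b.R1obs),
                    fm=0.5 * (a.fm + b.fm),
                    meta={"source": "augmented", "pair": (i, j)},
                )
            )
    return out


def fine_tune(
    model: TrainedRegressor,
    samples: list[Sample],
    epochs: int = 1000,
    seed: int = 0,
    model_cfg: ModelConfig = ModelConfig(),
) -> TrainedRegressor:
    """Continue optimizing an existing regressor on a new dataset.

    Weights and normalization carry over; ``epochs=0`` is the identity.
    """

    arrays = stack_samples(samples)
    mask = default_input_mask(samples[0].zspec.grid)
    if int(mask.sum()) != model.net.input_len:
        raise ValueError("fine-tuning dataset mask does not match the trained input")
    if epochs == 0:
        return model
    X = _input_matrix(arrays["z"], arrays["R1obs"], mask)
    y = arrays["target_A"] if model.target == "A" else arrays["target_W"]
    y_scaled = (y - model.y_mean) / model.y_std
    model.net.fit(
        model.transform(X), y_scaled,
        epochs=epochs,
        batch_size=model_cfg.batch_size,
        lr=model_cfg.learning_rate,
        seed=seed,
    )
    model.meta = dict(model.meta)
    model.meta["fine_tuned_epochs"] = epochs
    return model
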