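"""The scaled tissue-mimicking comparison study, reproducible end to end.

This module fixes the study conditions used to validate the package: a 3^3
tissue-mimicking grid (NOE(-1.6), amine and semi-solid MT pool sizes at
x{0.5, 1, 1.5} of the brain-model centre values), a 500-spectrum noisy test
set with analytic ground truth, a partially synthetic regressor trained on
10 000 samples, a fully simulated regressor trained on 3 000 Bloch spectra,
the six-pool Lorentzian baseline, an SNR sweep and a two-region phantom.
Both the acceptance tests and ``scripts/acceptance.py`` run the study through
these functions, so the reported numbers are recomputed from scratch under
one set of conditions.

The amine pool is among the varied parameters because its broad fast-exchange
peak extends into the upfield input range and is the main confound the
regressor must learn to separate from NOE(-1.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bloch import (
    default_brain_model,
    generate_dataset,
    simulate_zspectrum,
    tissue_mimicking_spec,
)
from .core import SaturationParams
from .dataset import Sample
from .evaluate import (
    assert_no_leakage,
    emulate_regime,
    phantom_map,
    snr_sweep,
    train_regime,
)
from .io import default_grid
from .lorentz import b0_correct, fit_multipool
from .quant import (
    CurriculumConfig,
    ModelConfig,
    TrainedRegressor,
    predict,
    train_curriculum,
)
from .synth import MeasuredComponents, SynthRanges, extract_components, sample_dataset

__all__ = ["StudyConfig", "Study"]

VARIED_PATHS = ("noe16.fs", "amine.fs", "mt.fs")


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and seeds of the scaled comparison study."""

    seed: int = 1
    n_test: int = 500
    n_partial: int = 10_000
    n_fully: int = 3_000
    n_clean_heldout: int = 1_000
    snr: float = 75.0
    snr_levels: tuple[float, ...] = (200.0, 100.0, 75.0, 50.0)
    epochs_first: int = 200
    epochs_later: int = 40

    def sub_seed(self, k: int) -> int:
        return (self.seed * 1000 + k) % (2**31 - 1)

    def model_config(self) -> ModelConfig:
        return ModelConfig(epochs_first=self.epochs_first, epochs_later=self.epochs_later)


class Study:
    """Lazy builder for the study's datasets, models and summaries.

    Every stage is computed on first access and cached, so tests can share
    one instance without recomputing the expensive trainings.
    """

    def __init__(self, config: StudyConfig = StudyConfig()):
        self.config = config
        self.sat = SaturationParams(B1_uT=1.0, t_sat=5.0)
        self.grid = default_grid()
        self._cache: dict = {}

    # -- datasets ------------------------------------------------------------
    @property
    def pool(self) -> list[Sample]:
        """All 27 grid combinations (noiseless, with ground truth)."""
        if "pool" not in self._cache:
            spec = tissue_mimicking_spec(
                self.sat, self.grid, n_select=None, seed=self.config.sub_seed(0),
                varied_paths=list(VARIED_PATHS),
            )
            self._cache["pool"] = generate_dataset(spec)
        return self._cache["pool"]

    @property
    def source(self) -> Sample:
        """The grid's centre combination: the measured-component source."""
        pool = self.pool
        centre = len(pool) // 2  # all-middle-levels combination of the 3^3 grid
        return pool[centre]

    @property
    def test_pool(self) -> list[Sample]:
        """Grid combinations available for testing (source excluded)."""
        src_id = self.source.zspec.meta["sample_id"]
        return [s for s in self.pool if s.zspec.meta["sample_id"] != src_id]

    @property
    def test_set(self) -> list[Sample]:
        """n_test draws (with replacement) from the test pool.

        Noise is added per evaluation, not here, so every SNR level sees the
        same underlying spectra.
        """
        if "test_set" not in self._cache:
            rng = np.random.default_rng(self.config.sub_seed(1))
            draws = rng.choice(len(self.test_pool), size=self.config.n_test)
            test = [self.test_pool[i] for i in draws]
            assert_no_leakage([self.source], test)
            self._cache["test_set"] = test
        return self._cache["test_set"]

    @property
    def components(self) -> MeasuredComponents:
        """Measured components extracted from the B0-corrected source spectrum."""
        if "components" not in self._cache:
            corrected, _ = b0_correct(self.source.zspec)
            fit = fit_multipool(corrected)
            self._cache["components"] = extract_components(
                corrected, fit, source_id="study-source"
            )
        return self._cache["components"]

    def partial_synth_samples(self, n: int, seed: int) -> list[Sample]:
        return sample_dataset(
            [self.components], SynthRanges(), n=n, seed=seed, sat=self.sat, grid=self.grid
        )

    # -- models ---------------------------------------------------------------
    @property
    def partial_model(self) -> TrainedRegressor:
        """Amplitude regressor trained on partially synthetic data."""
        if "partial_model" not in self._cache:
            train = self.partial_synth_samples(self.config.n_partial, self.config.sub_seed(2))
            model = train_curriculum(
                train, self.config.model_config(), CurriculumConfig(),
                target="A", seed=self.config.sub_seed(3),
            )
            model.meta["regime"] = "partial_synth"
            self._cache["partial_model"] = model
        return self._cache["partial_model"]

    @property
    def fully_simulated_model(self) -> TrainedRegressor:
        """Amplitude regressor trained on fully simulated data."""
        if "fully_model" not in self._cache:
            data = emulate_regime(
                "fully_simulated", [self.source], self.sat, self.grid,
                seed=self.config.sub_seed(4), n_train=self.config.n_fully,
                test=self.test_set,
            )
            self._cache["fully_model"] = train_regime(
                data, self.config.model_config(), CurriculumConfig(),
                target="A", seed=self.config.sub_seed(5),
            )
        return self._cache["fully_model"]

    def models(self) -> dict[str, TrainedRegressor]:
        return {
            "partial_synth": self.partial_model,
            "fully_simulated": self.fully_simulated_model,
        }

    # -- evaluations ------------------------------------------------------------
    def clean_heldout_mae(self) -> tuple[float, float]:
        """(mean |A_pred - A_true|, mean A_true) on held-out clean synthetic data."""
        heldout = self.partial_synth_samples(
            self.config.n_clean_heldout, self.config.sub_seed(6)
        )
        pred = predict(self.partial_model, heldout)
        truth = np.array([s.target_A for s in heldout])
        return float(np.abs(pred - truth).mean()), float(truth.mean())

    def sweep(self) -> pd.DataFrame:
        """Mean loss per method per SNR level (paired noise across methods/levels)."""
        if "sweep" not in self._cache:
            self._cache["sweep"] = snr_sweep(
                self.models(), self.test_set,
                snr_levels=self.config.snr_levels, seed=self.config.sub_seed(7),
            )
        return self._cache["sweep"]

    def mean_loss(self, method: str, snr: float | None = None) -> float:
        snr = self.config.snr if snr is None else snr
        df = self.sweep()
        row = df[(df["method"] == method) & (df["snr"] == snr)]
        if row.empty:
            raise KeyError(f"no sweep entry for {method} at SNR {snr}")
        return float(row["mean"].iloc[0])

    # -- phantom ------------------------------------------------------------------
    def phantom(self) -> tuple[np.ndarray, pd.DataFrame]:
        """3x3 two-region phantom: centre row is 'tumor' (NOE(-1.6) fs reduced 40%)."""
        if "phantom" not in self._cache:
            base = default_brain_model()
            tumor = base.replace_param("noe16.fs", base.pools["noe16"].fs * 0.6)
            labels = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0])
            zspecs = [
                simulate_zspectrum(
                    tumor if lab else base, self.sat, self.grid,
                    meta={"voxel": int(i), "sample_id": f"phantom{i}"},
                )
                for i, lab in enumerate(labels)
            ]
            pred, stats = phantom_map(
                self.partial_model, zspecs, labels,
                snr=200.0, seed=self.config.sub_seed(8),
            )
            self._cache["phantom"] = (pred, stats)
        return self._cache["phantom"]
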