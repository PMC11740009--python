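"""Multi-pool Bloch–McConnell simulation of CEST Z-spectra.

The simulator evolves the coupled magnetization of water plus up to six
solute pools under continuous-wave saturation and reads out the normalized
water longitudinal magnetization.  It produces the tissue-mimicking
validation spectra (with analytic ground truth for the NOE(-1.6) pool) and
the fully simulated training spectra.

The semi-solid MT pool is modelled as an ordinary Bloch–McConnell pool with a
very short T2 (Lorentzian lineshape); a super-Lorentzian lineshape is not
implemented.  Saturation is a single CW block starting from thermal
equilibrium, propagated with the matrix exponential of the time-invariant
augmented system — exact for CW irradiation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .core import OffsetGrid, PoolParams, SaturationParams, peak_width, rex
from .dataset import Sample, ZSpectrum

__all__ = [
    "WaterPool",
    "TissueModel",
    "SimDatasetSpec",
    "default_brain_model",
    "tissue_mimicking_spec",
    "assemble_bm_generator",
    "simulate_zspectrum",
    "generate_dataset",
    "perturb_parameters",
    "add_noise",
]


@dataclass(frozen=True)
class WaterPool:
    """Free water pool: longitudinal and transverse rates in s^-1."""

    R1w: float = 1.0 / 1.7
    R2w: float = 20.0

    def __post_init__(self) -> None:
        if self.R1w <= 0 or self.R2w <= 0:
            raise ValueError("water rates must be positive")


@dataclass(frozen=True)
class TissueModel:
    """Water plus solute pools plus a static-field offset.

    ``pools`` maps pool names to :class:`~cestnoe.core.PoolParams`; the
    semi-solid MT pool, when present, is the entry named ``"mt"`` and its
    ``fs`` is the pool size ratio ``fm``.
    """

    water: WaterPool
    pools: dict[str, PoolParams]
    b0_shift_ppm: float = 0.0

    @property
    def fm(self) -> float:
        mt = self.pools.get("mt")
        return mt.fs if mt is not None else 0.0

    @property
    def R1obs(self) -> float:
        # the observed water rate reported alongside simulated spectra
        return self.water.R1w

    def replace_param(self, path: str, value: float) -> "TissueModel":
        """Return a copy with one dotted-path parameter replaced.

        Paths: ``water.R1w``, ``water.R2w``, ``b0_shift_ppm``, or
        ``<pool>.<field>`` such as ``noe16.fs``.
        """

        if path == "b0_shift_ppm":
            return dataclasses.replace(self, b0_shift_ppm=float(value))
        head, _, attr = path.partition(".")
        if head == "water":
            if attr not in ("R1w", "R2w"):
                raise KeyError(f"unknown water field {attr!r}")
            return dataclasses.replace(
                self, water=dataclasses.replace(self.water, **{attr: float(value)})
            )
        if head not in self.pools:
            raise KeyError(f"unknown pool {head!r}")
        if attr not in ("fs", "ksw", "R2s", "delta_ppm", "R1s"):
            raise KeyError(f"unknown pool field {attr!r}")
        pools = dict(self.pools)
        pools[head] = dataclasses.replace(pools[head], **{attr: float(value)})
        return dataclasses.replace(self, pools=pools)


def default_brain_model(b0_shift_ppm: float = 0.0) -> TissueModel:
    """Seven-pool brain-like tissue model at 4.7 T.

    Amide (+3.5 ppm), amine (+3 ppm), guanidine (+2 ppm), NOE(-1.6),
    NOE(-3.5), semi-solid MT and water, with literature-typical rat-brain
    parameters (T1w 1.7 s, T2w 50 ms, MT T2s 10 us).
    """

    pools = {
        "amide": PoolParams("amide", fs=7.2e-4, ksw=30.0, R2s=30.0, delta_ppm=3.5),
        "amine": PoolParams("amine", fs=2.0e-3, ksw=3000.0, R2s=100.0, delta_ppm=3.0),
        "guan": PoolParams("guan", fs=1.0e-3, ksw=500.0, R2s=100.0, delta_ppm=2.0),
        "noe16": PoolParams("noe16", fs=2.0e-3, ksw=20.0, R2s=30.0, delta_ppm=-1.6),
        "noe35": PoolParams("noe35", fs=1.0e-2, ksw=20.0, R2s=30.0, delta_ppm=-3.5),
        "mt": PoolParams("mt", fs=0.07, ksw=25.0, R2s=1.0e5, delta_ppm=-2.5),
    }
    return TissueModel(water=WaterPool(), pools=pools, b0_shift_ppm=b0_shift_ppm)


def assemble_bm_generator(
    model: TissueModel, sat: SaturationParams, dw_radps: float, larmor_MHz: float
) -> np.ndarray:
    """Augmented Bloch–McConnell generator for one saturation offset.

    Returns the (3P+1) x (3P+1) matrix ``G`` such that ``d/dt [M; 1] = G [M; 1]``
    with M the per-pool (Mx, My, Mz) stack, water first.  Exchange is
    water-normalized: the water->solute rate is ``ksw * fs`` so detailed
    balance holds with equilibrium magnetizations (1, fs).
    """

    names = list(model.pools)
    n_pools = 1 + len(names)
    dim = 3 * n_pools
    G = np.zeros((dim + 1, dim + 1))
    w1 = sat.omega1

    deltas = [0.0] + [model.pools[n].delta_ppm for n in names]
    R1 = [model.water.R1w] + [model.pools[n].R1s for n in names]
    R2 = [model.water.R2w] + [model.pools[n].R2s for n in names]
    M0 = [1.0] + [model.pools[n].fs for n in names]

    for i in range(n_pools):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        theta = dw_radps - 2.0 * np.pi * larmor_MHz * deltas[i]
        G[x, x] -= R2[i]
        G[y, y] -= R2[i]
        G[z, z] -= R1[i]
        G[x, y] += theta
        G[y, x] -= theta
        G[y, z] += w1
        G[z, y] -= w1
        G[z, dim] += R1[i] * M0[i]

    # two-site exchange of each solute with water, component-wise
    for j, name in enumerate(names, start=1):
        pool = model.pools[name]
        kws = pool.ksw * pool.fs  # water -> solute
        for c in range(3):
            w, s = c, 3 * j + c
            G[w, w] -= kws
            G[w, s] += pool.ksw
            G[s, w] += kws
            G[s, s] -= pool.ksw
    return G


def simulate_zspectrum(
    model: TissueModel,
    sat: SaturationParams,
    grid: OffsetGrid,
    meta: dict | None = None,
) -> ZSpectrum:
    """Simulate a normalized Z-spectrum over the offset grid.

    Each offset is propagated from thermal equilibrium for ``sat.t_sat``
    seconds; the water Mz is read out and divided by its equilibrium value.
    A nonzero ``model.b0_shift_ppm`` shifts every applied offset
    (``dw -> dw + dw_shift``).
    """

    names = list(model.pools)
    dim = 3 * (1 + len(names))
    M0 = np.zeros(dim + 1)
    M0[2] = 1.0
    for j, name in enumerate(names, start=1):
        M0[3 * j + 2] = model.pools[name].fs
    M0[dim] = 1.0

    z = np.empty(len(grid))
    dws = grid.ppm_to_radps(grid.offsets_ppm + model.b0_shift_ppm)
    for i, dw in enumerate(dws):
        G = assemble_bm_generator(model, sat, dw, grid.larmor_MHz)
        try:
            M = expm(G * sat.t_sat) @ M0
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"propagation failed at offset index {i}") from exc
        z[i] = M[2]
    info = {"source": "simulated", "b0_shift_ppm": model.b0_shift_ppm}
    if meta:
        info.update(meta)
    return ZSpectrum(grid=grid, z=z, R1obs=model.R1obs, fm=model.fm, meta=info)


def ground_truth(model: TissueModel, sat: SaturationParams, grid: OffsetGrid) -> tuple[float, float]:
    """Analytic NOE(-1.6) amplitude (s^-1) and FWHM (ppm), B0 shift ignored."""

    pool = model.pools["noe16"]
    delta_radps = grid.ppm_to_radps(pool.delta_ppm)
    A = float(rex(pool, sat, delta_radps, grid.larmor_MHz))
    W = float(grid.radps_to_ppm(peak_width(pool, sat)))
    return A, W


@dataclass
class SimDatasetSpec:
    """Factorial (or randomly subsampled) Bloch–McConnell dataset spec.

    ``varied_params`` lists (dotted parameter path, levels); the full
    factorial over all levels is enumerated and ``n_select`` combinations are
    drawn with the stated seed (all of them if ``n_select`` is None).
    """

    template: TissueModel
    sat: SaturationParams
    grid: OffsetGrid
    varied_params: list[tuple[str, tuple]] = field(default_factory=list)
    n_select: int | None = None
    seed: int = 0
    max_size: int = 400_000

    def n_total(self) -> int:
        n = 1
        for _, levels in self.varied_params:
            if len(levels) == 0:
                raise ValueError("every varied parameter needs at least one level")
            n *= len(levels)
        return n


def tissue_mimicking_spec(
    sat: SaturationParams,
    grid: OffsetGrid,
    n_select: int | None = 1000,
    seed: int = 0,
    varied_paths: list[str] | None = None,
) -> SimDatasetSpec:
    """The tissue-mimicking validation grid: 11 parameters x 3 levels.

    Levels are x{0.5, 1, 1.5} of the brain-model centre values for the six
    pool sizes, NOE(-1.6) ksw and R2s, T1w and T2w (as rates: the level set
    of a rate is the reciprocal of the time-constant levels), and a B0 shift
    of {-0.05, 0, +0.05} ppm; 3^11 = 177147 combinations in total.
    ``varied_paths`` restricts the varied set (scaled-down grids for fast
    studies) while keeping the same levels per parameter.
    """

    model = default_brain_model()
    mult = (0.5, 1.0, 1.5)

    def scaled(path: str, centre: float) -> tuple[str, tuple]:
        return (path, tuple(m * centre for m in mult))

    levels: list[tuple[str, tuple]] = [
        scaled("amide.fs", model.pools["amide"].fs),
        scaled("amine.fs", model.pools["amine"].fs),
        scaled("guan.fs", model.pools["guan"].fs),
        scaled("noe16.fs", model.pools["noe16"].fs),
        scaled("noe35.fs", model.pools["noe35"].fs),
        scaled("mt.fs", model.pools["mt"].fs),
        scaled("noe16.ksw", model.pools["noe16"].ksw),
        scaled("noe16.R2s", model.pools["noe16"].R2s),
        # T1w, T2w varied as times => rates at 1/(m*T) = R/m
        ("water.R1w", tuple(model.water.R1w / m for m in mult)),
        ("water.R2w", tuple(model.water.R2w / m for m in mult)),
        ("b0_shift_ppm", (-0.05, 0.0, 0.05)),
    ]
    if varied_paths is not None:
        levels = [lv for lv in levels if lv[0] in varied_paths]
        missing = set(varied_paths) - {p for p, _ in levels}
        if missing:
            raise KeyError(f"unknown varied paths: {sorted(missing)}")
    return SimDatasetSpec(
        template=model,
        sat=sat,
        grid=grid,
        varied_params=levels,
        n_select=n_select,
        seed=seed,
    )


def generate_dataset(spec: SimDatasetSpec, override_cap: bool = False) -> list[Sample]:
    """Enumerate the factorial grid, select, simulate and label.

    Only the selected combinations are simulated.  Each sample carries the
    analytic ground-truth NOE(-1.6) amplitude and width computed with no B0
    shift, plus the flat parameter record in ``params``.
    """

    n_total = spec.n_total()
    if n_total > spec.max_size and not override_cap:
        raise ValueError(
            f"factorial size {n_total} exceeds cap {spec.max_size}; "
            "pass override_cap=True to proceed"
        )
    if spec.n_select is None:
        idx = np.arange(n_total)
    else:
        rng = np.random.default_rng(spec.seed)
        idx = np.sort(rng.choice(n_total, size=min(spec.n_select, n_total), replace=False))

    paths = [p for p, _ in spec.varied_params]
    level_sets = [levels for _, levels in spec.varied_params]
    sizes = [len(ls) for ls in level_sets]

    samples: list[Sample] = []
    for flat in idx:
        combo = []
        rem = int(flat)
        for size in reversed(sizes):
            combo.append(rem % size)
            rem //= size
        combo.reverse()
        model = spec.template
        record: dict[str, float] = {}
        for path, levels, k in zip(paths, level_sets, combo):
            model = model.replace_param(path, levels[k])
            record[path] = float(levels[k])
        zspec = simulate_zspectrum(model, spec.sat, spec.grid, meta={"sample_id": int(flat)})
        A, W = ground_truth(model, spec.sat, spec.grid)
        samples.append(Sample(zspec=zspec, target_A=A, target_W=W, params=record))
    return samples


def perturb_parameters(
    model: TissueModel,
    spread: float,
    which: list[str] | None = None,
    seed: int | np.random.Generator = 0,
    mode: str = "uniform",
) -> TissueModel:
    """Multiply selected parameters by independent random 1 +/- spread factors.

    ``mode="uniform"`` draws each multiplier from [1-spread, 1+spread];
    ``mode="binary"`` assigns either 1-spread or 1+spread with equal
    probability (a parameter is e.g. multiplied by 0.7 for one spectrum and by
    1.3 for another).  By default every solute-pool parameter (fs, ksw, R2s)
    of every pool except NOE(-1.6) is perturbed; the NOE(-1.6) pool and water
    are never touched by the default selector.  This is the per-spectrum
    variability used when emulating fully simulated training data.
    """

    if not 0 <= spread < 1:
        raise ValueError("spread must be in [0, 1)")
    if mode not in ("uniform", "binary"):
        raise ValueError("mode must be 'uniform' or 'binary'")
    if spread == 0:
        return model
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if which is None:
        which = [
            f"{name}.{attr}"
            for name in model.pools
            if name != "noe16"
            for attr in ("fs", "ksw", "R2s")
        ]
    out = model
    for path in which:
        head, _, attr = path.partition(".")
        base = (
            getattr(out.water, attr) if head == "water" else getattr(out.pools[head], attr)
        )
        if mode == "uniform":
            mult = rng.uniform(1.0 - spread, 1.0 + spread)
        else:
            mult = 1.0 - spread if rng.random() < 0.5 else 1.0 + spread
        out = out.replace_param(path, base * mult)
    return out


def add_noise(
    zspec: ZSpectrum, snr: float, seed: int | np.random.Generator = 0
) -> ZSpectrum:
    """Add zero-mean Gaussian noise with std 1/SNR to the normalized signal.

    SNR is defined on the S0-normalized scale, so sigma = 0.005 corresponds
    to SNR 200.  Deterministic under a fixed seed.
    """

    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = zspec.z + rng.normal(0.0, 1.0 / snr, size=zspec.z.shape)
    meta = dict(zspec.meta)
    meta["snr"] = float(snr)
    return ZSpectrum(grid=zspec.grid, z=noisy, R1obs=zspec.R1obs, fm=zspec.fm, meta=meta)
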