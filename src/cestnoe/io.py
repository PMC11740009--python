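"""Readers, writers and the seeded fixture generator.

Canonical interchange formats are plain text: Z-spectra as CSV
(``offset_ppm, z`` plus an optional ``voxel_id`` column) with a JSON sidecar
carrying ``R1obs``, ``fm`` and ``field_T``; datasets as NPZ archives;
measured components as NPZ.  Offsets are stored in ppm with the field
strength in metadata; negative ppm is upfield (the NOE side).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bloch import default_brain_model, simulate_zspectrum
from .core import OffsetGrid, SaturationParams, build_offset_grid
from .dataset import Sample, ZSpectrum, stack_samples
from .lorentz import fit_multipool
from .synth import SynthRanges, extract_components, sample_dataset

__all__ = [
    "default_grid",
    "write_zspectra",
    "read_zspectra",
    "save_dataset",
    "load_dataset",
    "save_components",
    "load_components",
    "make_fixtures",
]


def default_grid(field_T: float = 4.7) -> OffsetGrid:
    """The 89-point acquisition grid: 0.125 ppm on [-5, 5], 1.25 ppm outside."""
    return build_offset_grid(0.125, 1.25, (-5.0, 5.0), (-10.0, 10.0), field_T=field_T)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_zspectra(zspecs: list[ZSpectrum], path: str | Path) -> None:
    """Write one or more spectra sharing a grid to CSV + JSON sidecar."""
    path = Path(path)
    frames = []
    for i, zs in enumerate(zspecs):
        frames.append(
            pd.DataFrame(
                {"voxel_id": i, "offset_ppm": zs.grid.offsets_ppm, "z": zs.z}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    side = {
        "field_T": zspecs[0].grid.field_T,
        "R1obs": [zs.R1obs for zs in zspecs],
        "fm": [zs.fm for zs in zspecs],
        "meta": [
            {k: v for k, v in zs.meta.items() if isinstance(v, (str, int, float, bool))}
            for zs in zspecs
        ],
    }
    _sidecar(path).write_text(json.dumps(side, indent=2))


def read_zspectra(path: str | Path) -> list[ZSpectrum]:
    """Read spectra written by :func:`write_zspectra`; offsets are sorted."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("offset_ppm", "z"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if "voxel_id" not in df.columns:
        df["voxel_id"] = 0
    side = json.loads(_sidecar(path).read_text())
    out: list[ZSpectrum] = []
    for i, (_, group) in enumerate(df.groupby("voxel_id", sort=True)):
        group = group.sort_values("offset_ppm")
        grid = OffsetGrid(group["offset_ppm"].to_numpy(), field_T=side["field_T"])
        zs = ZSpectrum(
            grid=grid,
            z=group["z"].to_numpy(),
            R1obs=side["R1obs"][i],
            fm=side["fm"][i],
            meta=side.get("meta", [{}] * (i + 1))[i],
        )
        zs.validate()
        out.append(zs)
    return out


def save_dataset(samples: list[Sample], path: str | Path, provenance: dict | None = None) -> None:
    arrays = stack_samples(samples)
    arrays["provenance"] = np.str_(json.dumps(provenance or {}))
    np.savez_compressed(path, **arrays)


def load_dataset(path: str | Path) -> list[Sample]:
    blob = np.load(path, allow_pickle=False)
    grid = OffsetGrid(blob["offsets_ppm"], field_T=float(blob["field_T"]))
    prov = json.loads(str(blob["provenance"])) if "provenance" in blob else {}
    out = []
    for i in range(blob["z"].shape[0]):
        zs = ZSpectrum(
            grid=grid,
            z=blob["z"][i],
            R1obs=float(blob["R1obs"][i]),
            fm=float(blob["fm"][i]),
            meta=dict(prov, sample_index=i),
        )
        out.append(Sample(zspec=zs, target_A=float(blob["target_A"][i]),
                          target_W=float(blob["target_W"][i])))
    return out


def save_components(comp, path: str | Path) -> None:
    np.savez_compressed(
        path,
        offsets_ppm=comp.offsets_ppm,
        rex_noe35=comp.rex_noe35,
        rex_amine_guan=comp.rex_amine_guan,
        rex_mt=comp.rex_mt,
        R1obs=comp.R1obs,
        fm=comp.fm,
        source_id=np.str_(comp.source_id),
    )


def load_components(path: str | Path):
    from .synth import MeasuredComponents

    blob = np.load(path, allow_pickle=False)
    return MeasuredComponents(
        offsets_ppm=blob["offsets_ppm"],
        rex_noe35=blob["rex_noe35"],
        rex_amine_guan=blob["rex_amine_guan"],
        rex_mt=blob["rex_mt"],
        R1obs=float(blob["R1obs"]),
        fm=float(blob["fm"]),
        source_id=str(blob["source_id"]),
    )


def make_fixtures(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Generate the small seeded fixture bundle used in examples and tests.

    Contains a seven-pool brain-like spectrum, a two-pool analytic-check
    spectrum, a 3x3 two-region phantom (the centre-row "tumor" has reduced
    NOE(-1.6) pool size), and a 200-sample partially synthetic mini training
    set — all with analytic ground truth.
    """

    from .bloch import TissueModel, WaterPool, ground_truth
    from .core import PoolParams

    grid = default_grid()
    sat = SaturationParams(B1_uT=1.0, t_sat=5.0)
    brain = default_brain_model()
    brain_spec = simulate_zspectrum(brain, sat, grid, meta={"fixture": "brain7"})
    A_brain, W_brain = ground_truth(brain, sat, grid)

    twopool = TissueModel(
        water=WaterPool(R1w=0.6, R2w=25.0),
        pools={"noe16": PoolParams("noe16", fs=2e-3, ksw=20.0, R2s=30.0, delta_ppm=-1.6)},
    )
    twopool_spec = simulate_zspectrum(twopool, sat, grid, meta={"fixture": "twopool"})

    # 3x3 phantom: middle row mimics tumor (NOE(-1.6) fs reduced by 40%)
    labels = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0])
    tumor = brain.replace_param("noe16.fs", brain.pools["noe16"].fs * 0.6)
    phantom = [
        simulate_zspectrum(tumor if lab else brain, sat, grid,
                           meta={"fixture": "phantom", "voxel": int(i)})
        for i, lab in enumerate(labels)
    ]

    fit = fit_multipool(brain_spec)
    comp = extract_components(brain_spec, fit, source_id="fixture-brain7")
    mini_train = sample_dataset([comp], SynthRanges(), n=200, seed=seed, sat=sat, grid=grid)

    bundle = {
        "grid": grid,
        "sat": sat,
        "brain_model": brain,
        "brain_spectrum": brain_spec,
        "brain_truth": (A_brain, W_brain),
        "twopool_model": twopool,
        "twopool_spectrum": twopool_spec,
        "phantom": phantom,
        "phantom_labels": labels,
        "components": comp,
        "mini_train": mini_train,
        "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_zspectra([brain_spec], out / "brain7.csv")
        write_zspectra([twopool_spec], out / "twopool.csv")
        write_zspectra(phantom, out / "phantom.csv")
        np.savetxt(out / "phantom_labels.txt", labels, fmt="%d")
        save_components(comp, out / "components.npz")
        save_dataset(mini_train, out / "mini_train.npz",
                     provenance={"generator": "partial_synth", "seed": seed})
    return bundle
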