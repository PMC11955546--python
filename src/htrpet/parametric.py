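"""ROI extraction and voxel-wise AATH parametric mapping.

Regional curves are unweighted voxel means within a mask; the image-derived
input function (IDIF) is the same extraction over a blood-pool mask,
wrapped as an input function with whole blood equal to plasma.  Voxel-wise
mapping runs the basis-function grid search per voxel against one shared
basis cache (td/Tc at 0.5 s intervals by default) and emits 3-D maps of
CBF, K1, k2, Tc, td, E, PS and vb.  For freely diffusible tracers, E is
clipped at 99.9% before the Renkin-Crone inversion so PS maps stay finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import DynamicImage, InputFunction, TimeSeriesCurve
from .fitting import BasisSet, GridSpec, fit_many, precompute_bases
from .models import DEFAULT_FINE_DT, extraction_to_ps

__all__ = [
    "ParametricMaps",
    "extract_roi_tac",
    "extract_idif",
    "fit_voxelwise",
    "clip_extraction_for_ps",
]

MAP_NAMES = ("cbf", "k1", "k2", "tc", "td", "e", "ps", "vb")


def _check_mask(image: DynamicImage, mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.shape != image.data.shape[:3]:
        raise ValueError("mask geometry does not match the image")
    m = m != 0
    if not m.any():
        raise ValueError("mask is empty")
    return m


def extract_roi_tac(image: DynamicImage, mask: np.ndarray, label: str = "roi") -> TimeSeriesCurve:
    """Unweighted mean TAC over the nonzero voxels of ``mask``."""
    m = _check_mask(image, mask)
    return TimeSeriesCurve(image.schedule, image.data[m].mean(axis=0), label=label, noisy=True)


def extract_idif(image: DynamicImage, aorta_mask: np.ndarray) -> InputFunction:
    """Image-derived input function from a blood-pool mask.

    The extracted whole-blood curve doubles as the plasma curve (early-scan
    whole-blood = plasma assumption); attach a parent-fraction model
    afterwards if metabolite correction is needed.
    """
    tac = extract_roi_tac(image, aorta_mask, label="idif")
    wb = TimeSeriesCurve(image.schedule, np.clip(tac.values, 0, None), label="idif_whole_blood")
    return InputFunction(wb, wb.with_values(wb.values.copy(), label="idif_plasma"))


def clip_extraction_for_ps(
    e_map: np.ndarray, cbf_map: np.ndarray, clip: float = 0.999
) -> tuple[np.ndarray, np.ndarray]:
    """PS map from E and CBF maps with E clipped at ``clip`` (default 99.9%).

    The Renkin-Crone inversion PS = -CBF ln(1 - E) is indeterminate at
    E = 1; clipping keeps PS finite for freely diffusible tracers.  Returns
    (ps_map, clipped_mask).
    """
    e = np.asarray(e_map, dtype=float)
    if np.any(e > 1 + 1e-9) or np.any(e < 0):
        raise ValueError("E map values must lie in [0, 1]")
    clipped = e > clip
    ps = extraction_to_ps(np.minimum(e, clip), np.asarray(cbf_map, dtype=float))
    return ps, clipped


@dataclass
class ParametricMaps:
    """Voxel-wise 3-D kinetic maps sharing the input image geometry."""

    maps: dict[str, np.ndarray]
    validity: np.ndarray
    clipped: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    grid: GridSpec
    e_clip: float

    def save(self, out_dir: str | Path, prefix: str = "aath") -> None:
        """Write one NIfTI per map plus a JSON sidecar of settings/units."""
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        for name, arr in self.maps.items():
            nib.save(nib.Nifti1Image(arr.astype(np.float32), aff), str(out / f"{prefix}_{name}.nii.gz"))
        nib.save(nib.Nifti1Image(self.validity.astype(np.uint8), aff), str(out / f"{prefix}_validity.nii.gz"))
        sidecar = {
            "units": {
                "cbf": "ml/min/cm^3",
                "k1": "ml/min/cm^3",
                "k2": "1/min",
                "tc": "s",
                "td": "s",
                "e": "unitless",
                "ps": "ml/min/cm^3",
                "vb": "ml/cm^3",
            },
            "e_clip": self.e_clip,
            "grid": {
                "td_range_s": list(self.grid.td_range),
                "td_step_s": self.grid.td_step,
                "tc_range_s": list(self.grid.tc_range),
                "tc_step_s": self.grid.tc_step,
                "k2_range_per_min": list(self.grid.k2_range),
                "n_k2": self.grid.n_k2,
            },
        }
        (out / f"{prefix}_maps.json").write_text(json.dumps(sidecar, indent=2))


def fit_voxelwise(
    image: DynamicImage,
    input_function: InputFunction,
    spec: GridSpec | None = None,
    brain_mask: np.ndarray | None = None,
    smoothing_fwhm_mm: float | None = None,
    e_clip: float = 0.999,
    fine_dt: float = DEFAULT_FINE_DT,
    basis: BasisSet | None = None,
    chunk: int = 64,
) -> ParametricMaps:
    """Voxel-wise AATH mapping with the basis-function grid search.

    Bases are computed once for the (input, schedule, grid) combination and
    reused across voxels.  ``smoothing_fwhm_mm`` optionally applies spatial
    Gaussian smoothing to the dynamic image before fitting.  Voxels outside
    ``brain_mask`` are skipped; all-zero voxels are flagged invalid.
    """
    spec = spec or GridSpec.voxel()
    data = image.data
    if smoothing_fwhm_mm is not None and smoothing_fwhm_mm > 0:
        from scipy.ndimage import gaussian_filter

        sigma_vox = [smoothing_fwhm_mm / (2.3548 * v) for v in image.voxel_size_mm]
        data = np.stack(
            [gaussian_filter(data[..., m], sigma_vox) for m in range(data.shape[3])], axis=-1
        )
    if brain_mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        mask = _check_mask(image, brain_mask)
    tacs = data[mask]  # (n_voxels, M)
    nonzero = np.any(tacs != 0, axis=1)
    if basis is None:
        basis = precompute_bases(spec, input_function, image.schedule, "aath", fine_dt)
    res = fit_many(tacs[nonzero], basis, chunk=chunk)
    shape = data.shape[:3]
    maps = {name: np.zeros(shape) for name in MAP_NAMES}
    validity = np.zeros(shape, dtype=bool)
    vox_idx = np.flatnonzero(mask.ravel())
    fit_idx = vox_idx[nonzero]
    ps_fit, clipped_fit = clip_extraction_for_ps(res["e"], res["cbf"], clip=e_clip)
    values = {
        "cbf": res["cbf"],
        "k1": np.minimum(res["k1"], res["cbf"]),
        "k2": res["k2"],
        "tc": res["tc"],
        "td": res["td"],
        "e": res["e"],
        "ps": ps_fit,
        "vb": res["vb"],
    }
    for name, vals in values.items():
        flat = maps[name].ravel()
        flat[fit_idx] = vals
        maps[name] = flat.reshape(shape)
    vflat = validity.ravel()
    vflat[fit_idx] = True
    validity = vflat.reshape(shape)
    clipped = np.zeros(shape, dtype=bool)
    cflat = clipped.ravel()
    cflat[fit_idx] = clipped_fit
    clipped = cflat.reshape(shape)
    return ParametricMaps(maps, validity, clipped, image.voxel_size_mm, spec, e_clip)
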