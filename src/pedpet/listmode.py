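"""TOF list-mode data: container, forward simulation and binary file format.

A list-mode stream is an ordered sequence of fixed-size records.  Prompt
records carry a binned LOR coordinate (angle index, radial index) and a
signed TOF bin; time records carry a millisecond timestamp and are emitted
once per second of virtual acquisition; tag records carry an opaque payload.
The on-disk ``.plm`` format is a magic number, a JSON header block and
little-endian fixed-size records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any

import numpy as np
from numba import njit

from .phantom import PhantomImage, PatientMeta
from .projector import ScannerGeometry, get_system_matrix

__all__ = [
    "KIND_PROMPT", "KIND_TIME", "KIND_TAG",
    "RECORD_DTYPE", "ListModeData", "LmFormatError",
    "TruncatedFileError", "CountMismatchError", "UnknownRecordKindError",
    "forward_project", "simulate_listmode", "read_lm", "write_lm",
]

KIND_PROMPT = 0
KIND_TIME = 1
KIND_TAG = 2

#: prompt: a=angle index, b=radial index, c=signed TOF bin
#: time:   a=timestamp [ms];  tag: a=opaque payload
RECORD_DTYPE = np.dtype([("kind", "u1"), ("a", "<i4"), ("b", "<i4"), ("c", "<i4")])

_MAGIC = b"PLM1"


class LmFormatError(Exception):
    """Malformed list-mode file."""


class TruncatedFileError(LmFormatError):
    """File ends before the declared number of records."""


class CountMismatchError(LmFormatError):
    """Header-declared prompt/record counts disagree with the stream."""


class UnknownRecordKindError(LmFormatError):
    """Record with a kind byte outside {prompt, time, tag}."""


@dataclass
class ListModeData:
    """Ordered list-mode stream plus its acquisition header."""

    geometry: ScannerGeometry
    records: np.ndarray  # RECORD_DTYPE
    acquisition_duration: float = 120.0  # s (one 2-min bed position)
    count_level: float = 1.0
    count_scale: float = 1.0  # expected counts per (kBq/ml * mm) of line integral
    image_grid: tuple[int, float] = (200, 4.073)  # (matrix, voxel mm)
    source_meta: PatientMeta | None = None

    def __post_init__(self) -> None:
        self.records = np.ascontiguousarray(self.records, dtype=RECORD_DTYPE)

    @property
    def n_prompts(self) -> int:
        return int(np.count_nonzero(self.records["kind"] == KIND_PROMPT))

    @property
    def prompts(self) -> np.ndarray:
        return self.records[self.records["kind"] == KIND_PROMPT]

    def histogram(self, tof: bool = False) -> np.ndarray:
        """Histogram prompts into a sinogram.

        Returns (n_angles, n_radial) counts, or (n_angles, n_radial, n_tof)
        when ``tof`` is set.  Marginalising the TOF axis reproduces the
        non-TOF histogram exactly.
        """
        g = self.geometry
        p = self.prompts
        if tof:
            shape = (g.n_angles, g.n_radial_bins, g.n_tof_bins)
            idx = (p["a"].astype(np.int64) * g.n_radial_bins + p["b"]) * g.n_tof_bins \
                + (p["c"].astype(np.int64) + g.tof_half_bins)
        else:
            shape = (g.n_angles, g.n_radial_bins)
            idx = p["a"].astype(np.int64) * g.n_radial_bins + p["b"]
        out = np.bincount(idx, minlength=int(np.prod(shape)))
        return out.reshape(shape)

    def header_dict(self) -> dict[str, Any]:
        meta = None
        if self.source_meta is not None:
            m = self.source_meta
            meta = {
                "patient_id": m.patient_id, "weight": m.weight,
                "height": m.height, "bmi": m.bmi,
                "injected_activity": m.injected_activity,
                "age": m.age, "sex": m.sex, "n_lesions": m.n_lesions,
            }
        return {
            "geometry": self.geometry.to_dict(),
            "acquisition_duration": self.acquisition_duration,
            "count_level": self.count_level,
            "count_scale": self.count_scale,
            "image_grid": list(self.image_grid),
            "source_meta": meta,
            "n_records": int(self.records.shape[0]),
            "n_prompts": self.n_prompts,
        }


def forward_project(
    phantom: PhantomImage,
    geometry: ScannerGeometry,
    attenuate: bool = True,
    psf_fwhm: float | None = None,
) -> np.ndarray:
    """Expected line-integral sinogram of a phantom.

    Line integral of activity (kBq/ml * mm) per (angle, radial) bin; each
    LOR is multiplied by its attenuation survival factor when ``attenuate``
    is set; the activity is pre-blurred with an isotropic Gaussian of
    ``psf_fwhm`` mm when given (image-space resolution model).
    """
    if phantom.shape[0] != phantom.shape[1]:
        raise ValueError("phantom grid must be square")
    n_image = phantom.shape[0]
    voxel = phantom.voxel_size[0]
    sm = get_system_matrix(geometry, n_image, voxel)
    act = np.asarray(phantom.activity_map, dtype=float)
    if psf_fwhm:
        from .recon import gaussian_postfilter
        act = gaussian_postfilter(act, psf_fwhm, voxel, mode="constant")
    sino = sm.A @ act.ravel()
    if attenuate:
        sino = sino * sm.attenuation_factors(phantom.mu_map)
    return sino.reshape(geometry.n_angles, geometry.n_radial_bins)


@njit(cache=True)
def _sample_positions(indptr, indices, data, s_along, x, counts, u_voxel,
                      out_s):  # pragma: no cover
    """Sample a true emission position along the LOR for every prompt.

    For LOR l with ``counts[l]`` events, the emission pixel is drawn with
    probability proportional to (intersection length * activity); the
    event's position is the segment midpoint.
    """
    k = 0
    for lor in range(counts.shape[0]):
        c = counts[lor]
        if c == 0:
            continue
        lo = indptr[lor]
        hi = indptr[lor + 1]
        tot = 0.0
        for j in range(lo, hi):
            tot += data[j] * x[indices[j]]
        if tot <= 0.0:
            for _ in range(c):
                out_s[k] = 0.0
                k += 1
            continue
        for _ in range(c):
            target = u_voxel[k] * tot
            acc = 0.0
            pos = s_along[hi - 1]
            for j in range(lo, hi):
                acc += data[j] * x[indices[j]]
                if acc >= target:
                    pos = s_along[j]
                    break
            out_s[k] = pos
            k += 1
    return k


def simulate_listmode(
    phantom: PhantomImage,
    geometry: ScannerGeometry,
    target_prompts: int = 500_000,
    seed: int = 0,
    acquisition_duration: float = 120.0,
) -> ListModeData:
    """Forward-simulate a TOF list-mode acquisition of a phantom.

    Per-LOR counts are Poisson with mean proportional to the attenuated
    line-integral sinogram, normalised so the total expectation equals
    ``target_prompts``.  Each prompt's TOF bin is drawn from a Gaussian
    centred on the true emission position along the LOR with spatial FWHM
    c*tof_resolution/2, then discretised.  Prompts are shuffled into a
    random time order and interleaved with one time record per second.
    Reproducible from ``seed``.
    """
    if target_prompts <= 0:
        raise ValueError("target_prompts must be positive")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)
    n_image = phantom.shape[0]
    voxel = phantom.voxel_size[0]
    sm = get_system_matrix(geometry, n_image, voxel)

    sino = forward_project(phantom, geometry, attenuate=True).ravel()
    total = sino.sum()
    if total <= 0:
        scale = 1.0
        counts = np.zeros(sino.shape, dtype=np.int64)
    else:
        scale = target_prompts / total
        counts = rng.poisson(sino * scale).astype(np.int64)
    n_prompts = int(counts.sum())

    # true emission positions along each LOR (activity-weighted pixel choice)
    s_true = np.empty(n_prompts, dtype=np.float64)
    u_voxel = rng.random(n_prompts)
    _sample_positions(
        sm.A.indptr, sm.A.indices, sm.A.data, sm.s_along,
        phantom.activity_map.ravel().astype(np.float64), counts, u_voxel, s_true,
    )
    # measured TOF position = true + Gaussian timing blur, then binned
    s_meas = s_true + rng.normal(0.0, geometry.tof_sigma_mm, size=n_prompts)
    tof_bin = np.rint(s_meas / geometry.tof_bin_mm).astype(np.int64)
    half = geometry.tof_half_bins
    np.clip(tof_bin, -half, half, out=tof_bin)

    lor = np.repeat(np.arange(counts.shape[0], dtype=np.int64), counts)
    order = rng.permutation(n_prompts)
    prompts = np.empty(n_prompts, dtype=RECORD_DTYPE)
    prompts["kind"] = KIND_PROMPT
    prompts["a"] = (lor // geometry.n_radial_bins)[order]
    prompts["b"] = (lor % geometry.n_radial_bins)[order]
    prompts["c"] = tof_bin[order]

    # interleave one time record per elapsed second, prompts spread evenly
    n_sec = max(int(round(acquisition_duration)), 1)
    records = np.empty(n_prompts + n_sec, dtype=RECORD_DTYPE)
    bounds = np.linspace(0, n_prompts, n_sec + 1).astype(np.int64)
    k = 0
    for sec in range(n_sec):
        lo, hi = bounds[sec], bounds[sec + 1]
        records[k:k + hi - lo] = prompts[lo:hi]
        k += hi - lo
        records[k] = (KIND_TIME, (sec + 1) * 1000, 0, 0)
        k += 1

    return ListModeData(
        geometry=geometry,
        records=records,
        acquisition_duration=float(acquisition_duration),
        count_level=1.0,
        count_scale=scale,
        image_grid=(n_image, voxel),
        source_meta=phantom.meta,
    )


# ---------------------------------------------------------------------------
# .plm binary format
# ---------------------------------------------------------------------------

def write_lm(data: ListModeData, path) -> None:
    """Write a ``.plm`` file: magic, header length, JSON header, records."""
    header = json.dumps(data.header_dict()).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(np.uint32(len(header)).tobytes())
        fh.write(header)
        fh.write(data.records.tobytes())


def read_lm(path) -> ListModeData:
    """Read a ``.plm`` file; validates magic, record kinds and counts."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise LmFormatError(f"bad magic {magic!r}")
        raw_len = fh.read(4)
        if len(raw_len) < 4:
            raise TruncatedFileError("missing header length")
        hlen = int(np.frombuffer(raw_len, dtype=np.uint32)[0])
        hraw = fh.read(hlen)
        if len(hraw) < hlen:
            raise TruncatedFileError("truncated header")
        header = json.loads(hraw.decode())
        body = fh.read()
    n_records = header["n_records"]
    expected = n_records * RECORD_DTYPE.itemsize
    if len(body) < expected:
        raise TruncatedFileError(
            f"expected {expected} record bytes, found {len(body)}"
        )
    records = np.frombuffer(body[:expected], dtype=RECORD_DTYPE).copy()
    bad = ~np.isin(records["kind"], [KIND_PROMPT, KIND_TIME, KIND_TAG])
    if np.any(bad):
        raise UnknownRecordKindError(
            f"record kind {records['kind'][bad][0]} is not recognised"
        )
    n_prompts = int(np.count_nonzero(records["kind"] == KIND_PROMPT))
    if n_prompts != header["n_prompts"]:
        raise CountMismatchError(
            f"header declares {header['n_prompts']} prompts, stream has {n_prompts}"
        )
    meta = None
    if header.get("source_meta"):
        meta = PatientMeta(**header["source_meta"])
    grid = header.get("image_grid", [200, 4.073])
    return ListModeData(
        geometry=ScannerGeometry.from_dict(header["geometry"]),
        records=records,
        acquisition_duration=header["acquisition_duration"],
        count_level=header["count_level"],
        count_scale=header["count_scale"],
        image_grid=(int(grid[0]), float(grid[1])),
        source_meta=meta,
    )
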