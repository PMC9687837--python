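"""Synthetic paper-ECG sheet generator with ground-truth artifact masks.

Scanned clinical ECG sheets are ruled pages: a light millimetre grid, twelve
dark lead traces laid out in strips, and printed text in a header and footer
band. Every element that the preprocessing pipeline is meant to remove or
keep is drawn here from a known parametric model, so each rendered sheet
carries exact binary masks of its signal, grid, and label pixels.

Beat morphology is a five-component Gaussian sum (P, Q, R, S, T deflections)
plus an optional ST-segment offset, which is enough to give the five target
classes (normal, abnormal-rhythm, infarction, prior infarction, and a
COVID-19 surrogate) separable morphologies without claiming clinical
fidelity. Geometry follows standard ECG paper conventions: one minor grid
square is 1 mm = 0.04 s at 25 mm/s and 0.1 mV, so the pixel pitch of the
minor grid fixes both the time and voltage scales of the rendering.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .errors import ConfigurationError, LayoutError

#: Canonical class order used everywhere (manifests, confusion matrices).
CLASSES = ("NHB", "AHB", "MI", "HMI", "COVID")

#: Printed 12-lead order on a standard sheet.
LEAD_NAMES = (
    "I", "aVR", "V1", "V4",
    "II", "aVL", "V2", "V5",
    "III", "aVF", "V3", "V6",
)

_SECONDS_PER_MINOR = 0.04   # 25 mm/s paper speed, 1 mm minor square
_MV_PER_MINOR = 0.1         # 10 mm per mV gain


@dataclass(frozen=True)
class WaveformParams:
    """Parametric beat template.

    ``gauss_components`` holds ``(amplitude_mV, center_s, width_s)`` for the
    P, Q, R, S and T deflections, in that order, with centers measured from
    the start of the beat. ``st_offset`` (mV) is added only between the S and
    T centers; ``t_polarity`` multiplies the T amplitude (−1 renders an
    inverted T wave).
    """

    heart_rate: float = 72.0
    beat_jitter: float = 0.02
    gauss_components: tuple[tuple[float, float, float], ...] = (
        (0.15, 0.10, 0.025),   # P
        (-0.10, 0.20, 0.012),  # Q
        (1.00, 0.22, 0.020),   # R
        (-0.25, 0.24, 0.012),  # S
        (0.30, 0.40, 0.040),   # T
    )
    st_offset: float = 0.0
    t_polarity: int = 1
    baseline_wander_amp: float = 0.05
    trace_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ConfigurationError("heart_rate must be positive")
        if not (0.0 <= self.beat_jitter < 0.5):
            raise ConfigurationError("beat_jitter must lie in [0, 0.5)")
        if any(w <= 0 for _, _, w in self.gauss_components):
            raise ConfigurationError("Gaussian widths must be positive")
        if self.t_polarity not in (1, -1):
            raise ConfigurationError("t_polarity must be +1 or -1")

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class SheetSpec:
    """Page geometry of a rendered sheet.

    Defaults reproduce the source sheets: 2213x1572 px pages, a light-gray
    minor grid every 8 px with a darker major line every 5th minor, text
    bands at the top and bottom, and a 6x2 lead layout plus one full-width
    rhythm strip.
    """

    width_px: int = 2213
    height_px: int = 1572
    minor_grid_spacing_px: int = 8
    major_grid_every: int = 5
    grid_intensity: int = 210
    label_band_top_px: int = 170
    label_band_bottom_px: int = 170
    n_lead_rows: int = 6
    n_lead_cols: int = 2
    contrast_scale: float = 1.0
    page_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.contrast_scale <= 1.0):
            raise ConfigurationError("contrast_scale must be in (0, 1]")
        if not (0 <= self.grid_intensity <= 255):
            raise ConfigurationError("grid_intensity must be in [0, 255]")
        if self.minor_grid_spacing_px < 2:
            raise ConfigurationError("minor_grid_spacing_px must be >= 2")
        lead_h = self.height_px - self.label_band_top_px - self.label_band_bottom_px
        if lead_h <= 0:
            raise LayoutError("label bands overlap the lead area")
        if lead_h // (self.n_lead_rows + 1) < 6:
            raise LayoutError(
                f"lead area of {lead_h} px cannot hold "
                f"{self.n_lead_rows + 1} strips"
            )

    def scaled(self, factor: float) -> "SheetSpec":
        """Return a geometrically similar sheet at ``factor`` linear scale."""
        return replace(
            self,
            width_px=max(1, round(self.width_px * factor)),
            height_px=max(1, round(self.height_px * factor)),
            minor_grid_spacing_px=max(2, round(self.minor_grid_spacing_px * factor)),
            label_band_top_px=max(8, round(self.label_band_top_px * factor)),
            label_band_bottom_px=max(8, round(self.label_band_bottom_px * factor)),
        )


@dataclass
class SyntheticSample:
    """A rendered sheet plus its ground truth.

    ``image`` is an 8-bit grayscale page (origin top-left). The three masks
    mark the pixels of each drawn element and are mutually exclusive.
    ``strips`` records, for every lead strip, ``(y0, y1, x0, x1, baseline_row)``
    in image coordinates; the last strip is the full-width rhythm strip.
    """

    image: np.ndarray
    signal_mask: np.ndarray
    grid_mask: np.ndarray
    label_mask: np.ndarray
    class_label: str
    params: tuple[WaveformParams, SheetSpec]
    strips: list[tuple[int, int, int, int, int]] = field(default_factory=list)


def synth_beat(t, params: WaveformParams):
    """Evaluate the beat template at time ``t`` (seconds from beat onset).

    Returns the amplitude in mV: the Gaussian-sum of the five deflections,
    with ``st_offset`` added only on the S-center..T-center interval.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    comps = params.gauss_components
    for i, (a, mu, sigma) in enumerate(comps):
        if i == 4:
            a = a * params.t_polarity
        out = out + a * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))
    if params.st_offset != 0.0 and len(comps) >= 5:
        s_center = comps[3][1]
        t_center = comps[4][1]
        window = (t >= s_center) & (t <= t_center)
        out = out + np.where(window, params.st_offset, 0.0)
    return out if out.ndim else float(out)


def class_waveform_params(class_label: str, rng: np.random.Generator) -> WaveformParams:
    """Draw waveform parameters from the class-conditional prior.

    The priors are deliberately simple surrogates: NHB is the baseline
    template; AHB has a strongly irregular RR interval; MI has ST elevation
    and a deepened Q; HMI has a pathological Q with an inverted T; the
    COVID-19 surrogate has an elevated rate with a damped T wave.
    """
    if class_label not in CLASSES:
        raise ConfigurationError(f"unknown class label {class_label!r}")
    base = WaveformParams()
    comps = [list(c) for c in base.gauss_components]
    if class_label == "NHB":
        hr = rng.normal(72.0, 3.0)
        jitter, st, pol = 0.02, 0.0, 1
    elif class_label == "AHB":
        hr = rng.normal(80.0, 6.0)
        jitter, st, pol = 0.30, 0.0, 1
    elif class_label == "MI":
        hr = rng.normal(76.0, 3.0)
        jitter, st, pol = 0.02, 0.30, 1
        comps[1][0] = -0.40          # deep Q
    elif class_label == "HMI":
        hr = rng.normal(70.0, 3.0)
        jitter, st, pol = 0.02, 0.0, -1
        comps[1][0] = -0.45          # pathological Q
    else:  # COVID surrogate
        hr = rng.normal(112.0, 5.0)
        jitter, st, pol = 0.02, 0.0, 1
        comps[4][0] = 0.08           # damped T
    hr = float(np.clip(hr, 40.0, 160.0))
    return replace(
        base,
        heart_rate=hr,
        beat_jitter=jitter,
        gauss_components=tuple(tuple(c) for c in comps),
        st_offset=st,
        t_polarity=pol,
    )


def _beat_starts(rng: np.random.Generator, period: float, jitter: float,
                 duration: float) -> np.ndarray:
    starts = [0.0]
    while starts[-1] < duration:
        step = period * (1.0 + jitter * rng.uniform(-1.0, 1.0))
        starts.append(starts[-1] + max(step, 0.05))
    return np.asarray(starts)


def _trace_rows(wf: WaveformParams, rng: np.random.Generator, n_cols: int,
                px_per_s: float, px_per_mv: float, amp_scale: float) -> np.ndarray:
    """Amplitude of one strip's trace, in pixels below(-)/above(+) baseline."""
    t = np.arange(n_cols) / px_per_s
    duration = t[-1] if n_cols else 0.0
    starts = _beat_starts(rng, wf.beat_period, wf.beat_jitter, duration + wf.beat_period)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
    local = t - starts[idx]
    amp = synth_beat(local, wf) * amp_scale
    phase = rng.uniform(0, 2 * np.pi)
    amp = amp + wf.baseline_wander_amp * np.sin(2 * np.pi * 0.4 * t + phase)
    amp = amp + rng.normal(0.0, wf.trace_noise_sd, size=n_cols)
    return amp * px_per_mv


def _strip_layout(sheet: SheetSpec) -> list[tuple[int, int, int, int]]:
    """(y0, y1, x0, x1) for each lead strip; last entry is the rhythm strip."""
    top = sheet.label_band_top_px
    bottom = sheet.height_px - sheet.label_band_bottom_px
    slots = sheet.n_lead_rows + 1  # lead rows + rhythm strip
    strip_h = (bottom - top) // slots
    if strip_h < 6:
        raise LayoutError(
            f"lead area of {bottom - top} px cannot hold {slots} strips"
        )
    col_w = sheet.width_px // sheet.n_lead_cols
    strips = []
    for r in range(sheet.n_lead_rows):
        y0 = top + r * strip_h
        for c in range(sheet.n_lead_cols):
            strips.append((y0, y0 + strip_h, c * col_w, (c + 1) * col_w))
    y0 = top + sheet.n_lead_rows * strip_h
    strips.append((y0, y0 + strip_h, 0, sheet.width_px))
    return strips


def render_sheet(class_label: str, sheet: SheetSpec, wf: WaveformParams,
                 seed: int) -> SyntheticSample:
    """Render one sheet deterministically from ``seed``.

    Drawing order is grid, labels, traces; the image composites by darkness
    (ink wins over grid) and the masks are made mutually exclusive with the
    same priority. Page-level contrast scaling and additive scanner noise are
    applied last so they affect every element alike.
    """
    if class_label not in CLASSES:
        raise ConfigurationError(f"unknown class label {class_label!r}")
    rng = np.random.default_rng(seed)
    H, W = sheet.height_px, sheet.width_px
    spacing = sheet.minor_grid_spacing_px
    px_per_s = spacing / _SECONDS_PER_MINOR
    px_per_mv = spacing / _MV_PER_MINOR

    # --- grid ---------------------------------------------------------------
    top = sheet.label_band_top_px
    bottom = H - sheet.label_band_bottom_px
    grid = np.zeros((H, W), dtype=bool)
    major = np.zeros((H, W), dtype=bool)
    for y in range(top, bottom, spacing):
        grid[y, :] = True
        if (y - top) // spacing % sheet.major_grid_every == 0:
            major[y, :] = True
    for x in range(0, W, spacing):
        grid[top:bottom, x] = True
        if x // spacing % sheet.major_grid_every == 0:
            major[top:bottom, x] = True
    minor_val = float(sheet.grid_intensity)
    major_val = float(max(0, 255 - 2 * (255 - sheet.grid_intensity)))

    # --- labels -------------------------------------------------------------
    label_img = Image.new("L", (W, H), 255)
    draw = ImageDraw.Draw(label_img)
    header = f"ID {seed % 100000:05d}   12-lead ECG   25 mm/s  10 mm/mV"
    footer = "Leads: " + " ".join(LEAD_NAMES)
    band_h = min(sheet.label_band_top_px, sheet.label_band_bottom_px)
    y_head = max(2, sheet.label_band_top_px // 3)
    draw.text((10, y_head), header, fill=0)
    draw.text((10, H - sheet.label_band_bottom_px + max(2, band_h // 3)),
              footer, fill=0)
    label_mask = np.asarray(label_img) < 128

    # --- traces -------------------------------------------------------------
    strips = _strip_layout(sheet)
    trace_img = Image.new("L", (W, H), 255)
    tdraw = ImageDraw.Draw(trace_img)
    trace_width = max(3, (spacing + 2) // 3)
    strip_meta = []
    for k, (y0, y1, x0, x1) in enumerate(strips):
        baseline = y0 + int(0.65 * (y1 - y0))
        amp_scale = 1.0 if k == len(strips) - 1 else (0.6 + 0.5 * rng.uniform())
        rows = _trace_rows(wf, rng, x1 - x0, px_per_s, px_per_mv, amp_scale)
        ys = np.clip(baseline - rows, y0 + 1, y1 - 2)
        pts = [(x0 + i, float(ys[i])) for i in range(x1 - x0)]
        if len(pts) >= 2:
            tdraw.line(pts, fill=0, width=trace_width)
        strip_meta.append((y0, y1, x0, x1, baseline))
    signal_mask = np.asarray(trace_img) < 128

    # --- composite ----------------------------------------------------------
    img = np.full((H, W), 255.0)
    img[grid & ~major] = minor_val
    img[major] = major_val
    img[label_mask] = 30.0
    img[signal_mask] = 20.0
    img = 255.0 - sheet.contrast_scale * (255.0 - img)
    if sheet.page_noise_sd > 0:
        img = img + rng.normal(0.0, sheet.page_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    grid_mask = grid & ~signal_mask & ~label_mask
    label_mask = label_mask & ~signal_mask
    return SyntheticSample(
        image=img,
        signal_mask=signal_mask,
        grid_mask=grid_mask,
        label_mask=label_mask,
        class_label=class_label,
        params=(wf, sheet),
        strips=strip_meta,
    )


def morphology_features(sample: SyntheticSample) -> np.ndarray:
    """Summary features of the rhythm strip used for separability checks.

    Returns ``[peaks_per_s, rr_cv, mean_offset_mv, neg_frac, pos_frac]``:
    R-peak rate, coefficient of variation of RR intervals, mean vertical
    trace offset from baseline in mV, and fractions of columns deflected
    more than 0.15 mV below/above baseline.
    """
    wf, sheet = sample.params
    spacing = sheet.minor_grid_spacing_px
    px_per_s = spacing / _SECONDS_PER_MINOR
    px_per_mv = spacing / _MV_PER_MINOR
    y0, y1, x0, x1, baseline = sample.strips[-1]
    strip = sample.signal_mask[y0:y1, x0:x1]
    cols = strip.any(axis=0)
    rows = np.arange(y0, y1, dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        centroid = (strip * rows).sum(axis=0) / np.maximum(strip.sum(axis=0), 1)
    center_mv = (baseline - centroid) / px_per_mv
    center_mv[~cols] = 0.0
    # per-column extreme excursions of the ink (top = upward, in mV)
    row_idx = np.broadcast_to(rows, strip.shape)
    top = np.where(cols, baseline - np.where(strip, row_idx, np.inf).min(axis=0), 0.0)
    bot = np.where(cols, baseline - np.where(strip, row_idx, -np.inf).max(axis=0), 0.0)
    top_mv, bot_mv = top / px_per_mv, bot / px_per_mv
    duration = (x1 - x0) / px_per_s

    high = top_mv > 0.6  # R-peak excursions
    starts = np.flatnonzero(high[1:] & ~high[:-1])
    peaks_per_s = len(starts) / duration
    if len(starts) >= 3:
        rr = np.diff(starts) / px_per_s
        rr_cv = float(np.std(rr) / np.mean(rr))
    else:
        rr_cv = 0.0
    return np.array([
        peaks_per_s,
        rr_cv,
        float(center_mv[cols].mean()) if cols.any() else 0.0,
        float((bot_mv < -0.25).mean()),
        float((top_mv > 0.15).mean()),
    ])


def _save_masks_png(path: Path, sample: SyntheticSample) -> None:
    rgb = np.stack(
        [sample.signal_mask, sample.grid_mask, sample.label_mask], axis=-1
    ).astype(np.uint8) * 255
    Image.fromarray(rgb, mode="RGB").save(path)


def generate_dataset(per_class_counts: Mapping[str, int], out_dir,
                     seed: int, sheet: SheetSpec | None = None):
    """Render a dataset and write images, masks, and a JSON-lines manifest.

    Per-image seeds are ``seed + index`` with ``index`` counting over classes
    in :data:`CLASSES` order, which makes the dataset a pure function of
    ``(counts, seed)``. Returns the manifest as a :class:`pandas.DataFrame`
    with columns ``image_id, path, class, seed``.
    """
    import pandas as pd

    sheet = sheet if sheet is not None else SheetSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for label in per_class_counts:
        if label not in CLASSES:
            raise ConfigurationError(f"unknown class label {label!r}")
        if per_class_counts[label] < 0:
            raise ConfigurationError("counts must be >= 0")

    rows = []
    index = 0
    for label in CLASSES:
        for _ in range(int(per_class_counts.get(label, 0))):
            img_seed = seed + index
            wf_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=img_seed, spawn_key=(1,))
            )
            wf = class_waveform_params(label, wf_rng)
            sample = render_sheet(label, sheet, wf, seed=img_seed)
            image_id = f"{label.lower()}_{index:05d}"
            img_path = out_dir / f"{image_id}.png"
            Image.fromarray(sample.image, mode="L").save(img_path)
            _save_masks_png(out_dir / f"{image_id}_masks.png", sample)
            rows.append({
                "image_id": image_id,
                "path": img_path.name,
                "class": label,
                "seed": img_seed,
            })
            index += 1

    manifest = pd.DataFrame(
        rows, columns=["image_id", "path", "class", "seed"]
    )
    with open(out_dir / "manifest.jsonl", "w") as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")
    return manifest


def dataset_checksum(out_dir) -> int:
    """CRC32 over every PNG and the manifest, for reproducibility checks."""
    out_dir = Path(out_dir)
    crc = 0
    for path in sorted(out_dir.iterdir()):
        if path.suffix in {".png", ".jsonl"}:
            crc = zlib.crc32(path.read_bytes(), crc)
    return crc
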