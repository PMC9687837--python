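import numpy as np
import pytest

from paperecg import preprocess, synthio


def render_class_sample(label: str, sheet: synthio.SheetSpec, seed: int) -> synthio.SyntheticSample:
    """Render one sheet with class-prior waveform parameters (seeded)."""
    wf_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    )
    wf = synthio.class_waveform_params(label, wf_rng)
    return synthio.render_sheet(label, sheet, wf, seed=seed)


def line_removal_rates(sample: synthio.SyntheticSample,
                       cfg: preprocess.PipelineConfig) -> tuple[float, float]:
    """(fraction of grid pixels removed, fraction of signal pixels retained)
    after the crop -> Otsu -> open -> small-component-removal stages."""
    cropped = preprocess.crop_labels(sample.image, cfg)
    grid = preprocess.crop_labels(
        sample.grid_mask.astype(np.uint8) * 255, cfg) == 255
    signal = preprocess.crop_labels(
        sample.signal_mask.astype(np.uint8) * 255, cfg) == 255
    binary = preprocess.otsu_threshold(cropped).binary
    opened = preprocess.morph_open(binary, cfg.morph_kernel)
    small = preprocess.find_small_components(opened, cfg.contour_area_max)
    cleaned = preprocess.remove_components(opened, small) == 255
    return float(1.0 - cleaned[grid].mean()), float(cleaned[signal].mean())


@pytest.fixture(scope="session")
def half_sheet() -> synthio.SheetSpec:
    return synthio.SheetSpec().scaled(0.5)


@pytest.fixture(scope="session")
def quarter_sheet() -> synthio.SheetSpec:
    return synthio.SheetSpec().scaled(0.25)


@pytest.fixture(scope="session")
def half_sample(half_sheet) -> synthio.SyntheticSample:
    return render_class_sample("NHB", half_sheet, seed=7)
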