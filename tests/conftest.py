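import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from islethull.masking import BinaryMask
from islethull.pipeline import RunConfig, analyze_cohort
from islethull.synthetic import CHANNELS, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CHANNEL_MAP = {role: i for i, role in enumerate(CHANNELS)}


def disk_grid(radius: float, n: int | None = None, center=None) -> np.ndarray:
    """Boolean disk: pixel centres within ``radius`` of ``center``."""
    n = n or 2 * (int(np.ceil(radius)) + 4)
    cx, cy = center or (n / 2, n / 2)
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2


def blob_grid(rng: np.random.Generator, n: int = 96, n_disks: int = 4,
              r_lo: float = 10, r_hi: float = 30) -> np.ndarray:
    """Random union of disks — an irregular, generally concave mask."""
    g = np.zeros((n, n), dtype=bool)
    for _ in range(n_disks):
        r = rng.uniform(r_lo, r_hi)
        cx = rng.uniform(r + 1, n - r - 1)
        cy = rng.uniform(r + 1, n - r - 1)
        g |= disk_grid(r, n, center=(cx, cy))
    return g


def mask_of(grid: np.ndarray, um_per_px: float = 1.0, tag: str = "") -> BinaryMask:
    return BinaryMask(grid, um_per_px, tag)


def crescent_grid(r: float = 20, offset: float = 12, n: int = 64) -> np.ndarray:
    """Disk minus the same disk shifted: the canonical concave test shape."""
    c = n / 2
    return disk_grid(r, n, center=(c, c)) & ~disk_grid(r, n, center=(c + offset, c))


def default_config(um_per_px: float) -> RunConfig:
    return RunConfig(channel_map=dict(CHANNEL_MAP), um_per_px=um_per_px)


@pytest.fixture(scope="session")
def adult_run(tmp_path_factory):
    """A simulated 3-mouse x 10-islet cohort analyzed end-to-end."""
    data = tmp_path_factory.mktemp("adult_data")
    out = tmp_path_factory.mktemp("adult_out")
    simulate_cohort("adult_nondiabetic", 3, 10, 11, data)
    cfg = RunConfig.from_yaml(data / "config.yaml")
    df = analyze_cohort(data, out, cfg, write_overlays=False)
    return data, out, df


@pytest.fixture(scope="session")
def ragko_run(tmp_path_factory):
    """A lymphocyte-free cohort with bleed-through: the false-positive control."""
    data = tmp_path_factory.mktemp("ragko_data")
    out = tmp_path_factory.mktemp("ragko_out")
    simulate_cohort("rag_ko", 3, 10, 13, data)
    cfg = RunConfig.from_yaml(data / "config.yaml")
    df = analyze_cohort(data, out, cfg, write_overlays=False)
    return data, out, df
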