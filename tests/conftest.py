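import numpy as np
import pytest

from cerephys import synthdata as sd
from cerephys import spike_detect as det


@pytest.fixture(scope="session")
def templates():
    return sd.default_templates()


@pytest.fixture(scope="session")
def purkinje_cell():
    """One awake control Purkinje cell, 60 s, with ground-truth trains."""
    spec = sd.awake_purkinje_cohort(1, n_cells_per_group=1, duration_s=60.0)
    return sd.gen_cohort(spec).cells[0]


@pytest.fixture(scope="session")
def snr8_trace(purkinje_cell, templates):
    """Band-passed synthetic trace of the fixture cell at SNR 8."""
    noise = sd.noise_sd_for_snr(templates, 8.0)
    return sd.synth_trace(purkinje_cell, templates, noise_sd=noise, seed=101)


@pytest.fixture(scope="session")
def snr8_sorted(snr8_trace):
    return det.sort_trace(snr8_trace)


def f1_score(tp: int, fp: int, fn: int) -> float:
    return 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else float("nan")


def brute_force_count(mask: np.ndarray, min_size: int = 1) -> int:
    """Independent 8-connected component count by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    count = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    a, b = stack.pop()
                    size += 1
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if (0 <= x < mask.shape[0]
                                    and 0 <= y < mask.shape[1]
                                    and mask[x, y] and not seen[x, y]):
                                seen[x, y] = True
                                stack.append((x, y))
                if size >= min_size:
                    count += 1
    return count
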