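"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

from fkmeans.io import LabelMask
from fkmeans.phantom import SMALL_SPEC_KW, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def naive_fd_map():
    """Literal double-loop box-counting FD with an explicit polyfit
    regression — the independent reference implementation."""

    def compute(image, R):
        nx, ny = image.shape
        rs = list(range(3, R))
        out = np.zeros((nx, ny))
        for x in range(nx):
            for y in range(ny):
                log_inv_r, log_nr = [], []
                for r in rs:
                    if r % 2:
                        lo_x, hi_x = x - (r - 1) // 2, x + (r - 1) // 2
                        lo_y, hi_y = y - (r - 1) // 2, y + (r - 1) // 2
                    else:
                        lo_x, hi_x = x - (r // 2 - 1), x + r // 2
                        lo_y, hi_y = y - (r // 2 - 1), y + r // 2
                    win = image[max(lo_x, 0):hi_x + 1, max(lo_y, 0):hi_y + 1]
                    nr = (R ** 2 / r ** 2) * (win.max() - win.min()) / r + 1.0
                    log_inv_r.append(np.log(1.0 / r))
                    log_nr.append(np.log(nr))
                out[x, y] = np.polyfit(log_inv_r, log_nr, 1)[0]
        return out

    return compute


@pytest.fixture(scope="session")
def small_phantom():
    """48x48x16 phantom with all structures planted (volume, label mask)."""
    spec = PhantomSpec(seed=11, fibrosis_fraction=0.1, **SMALL_SPEC_KW)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom_clip(small_phantom):
    """Small phantom plus the over-inclusive LA mask used as clipping input."""
    volume, mask = small_phantom
    union = (mask.data > 0).astype(np.int32)
    la_in = LabelMask(data=union, label_map={"background": 0, "la": 1},
                      spacing=mask.spacing)
    return volume, la_in, mask
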