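"""Shared fixtures and benchmark-domain helpers."""

from __future__ import annotations

import numpy as np
import pytest

from atriastasis.geometry import ChamberSpec, generate_chamber_series


def rect_boundary(L, H, h, left="inlet", right="outlet"):
    """Labelled CCW rectangle boundary: bottom/top walls, left/right
    openings (relabel afterwards for other setups)."""
    nx, ny = max(int(L / h), 1), max(int(H / h), 1)
    pts, labs = [], []
    for i in range(nx):
        pts.append([i * L / nx, 0.0])
        labs.append("wall")
    for j in range(ny):
        pts.append([L, j * H / ny])
        labs.append(right)
    for i in range(nx):
        pts.append([L - i * L / nx, H])
        labs.append("wall")
    for j in range(ny):
        pts.append([0.0, H - j * H / ny])
        labs.append(left)
    return np.asarray(pts, float), np.asarray(labs)


@pytest.fixture(scope="session")
def control_spec():
    return ChamberSpec()


@pytest.fixture(scope="session")
def control_series(control_spec):
    return generate_chamber_series(control_spec)


@pytest.fixture(scope="session")
def af_spec():
    # group-mean AF-like subject (indexed volumes x mean BSA)
    return ChamberSpec(
        la_max_volume=66 * 2.02,
        la_ef=0.43,
        laa_max_volume=6 * 2.02,
        laa_ef=0.62,
        lv_edv=78 * 2.02,
        lv_esv=26 * 2.02,
        heart_rate=62.0,
        bsa=2.02,
    )
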