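import numpy as np
import pytest

from aggflow.imaging import VoxelGrid
from aggflow.flow import FlowField


def staggered_from_functions(grid: VoxelGrid, fu, fv, fw) -> FlowField:
    """Sample analytic velocity components on their staggered face positions."""
    nx, ny, nz = grid.shape
    h = grid.h
    xf = np.arange(nx + 1) * h
    yf = np.arange(ny + 1) * h
    zf = np.arange(nz + 1) * h
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    zc = (np.arange(nz) + 0.5) * h
    u = fu(xf[:, None, None], yc[None, :, None], zc[None, None, :])
    v = fv(xc[:, None, None], yf[None, :, None], zc[None, None, :])
    w = fw(xc[:, None, None], yc[None, :, None], zf[None, None, :])
    u = np.broadcast_to(u, (nx + 1, ny, nz)).astype(float).copy()
    v = np.broadcast_to(v, (nx, ny + 1, nz)).astype(float).copy()
    w = np.broadcast_to(w, (nx, ny, nz + 1)).astype(float).copy()
    return FlowField(u, v, w, np.zeros((nx, ny, nz)), grid, v_ref=1.0)


@pytest.fixture
def small_grid():
    return VoxelGrid((6, 8, 10), 0.01)
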