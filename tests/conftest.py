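import numpy as np
import pytest

from smfret_curate.crossover import CrossoverProfile
from smfret_curate.model import DonorAcceptorTrajectory


def make_trajectory(
    n=30,
    traj_id="t0",
    cell_id="cell0",
    condition="apo",
    seed=0,
    acc_intensity=None,
    don_intensity=None,
    start_frame=0,
):
    """A small random trajectory for unit tests."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(10, 50, size=(n, 2))
    acc = rng.uniform(100, 900, n) if acc_intensity is None else np.asarray(acc_intensity, float)
    don = rng.uniform(100, 900, n) if don_intensity is None else np.asarray(don_intensity, float)
    return DonorAcceptorTrajectory(
        id=traj_id,
        cell_id=cell_id,
        condition=condition,
        frames=start_frame + np.arange(n),
        acceptor_xy=xy,
        donor_xy=xy.copy(),
        acceptor_intensity=acc,
        donor_intensity=don,
    )


def make_profile(traj, keep=None, rho_acc=None, rho_don=None):
    n = len(traj)
    if keep is None:
        keep = np.ones(n, dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    if rho_acc is None:
        rho_acc = np.where(keep, 1, 2)
    if rho_don is None:
        rho_don = np.ones(n, dtype=np.int64)
    return CrossoverProfile(
        traj_id=traj.id,
        frames=traj.frames.copy(),
        rho_acceptor=np.asarray(rho_acc, dtype=np.int64),
        rho_donor=np.asarray(rho_don, dtype=np.int64),
        keep_mask=keep,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
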