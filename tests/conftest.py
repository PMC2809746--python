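import numpy as np
import pytest

from synbow.neuropil import (
    SizeDistribution,
    SynapseDisk,
    VolumeSpec,
    assign_connectivity,
    sample_synapse_centers,
    sample_synapse_geometry,
)
from synbow.optics import OperatingPoint, PSFSpec


@pytest.fixture
def small_volume():
    return VolumeSpec(extents_um=(3.0, 3.0, 2.0), voxel_size_um=(0.05, 0.05, 0.05))


@pytest.fixture
def op_default():
    return OperatingPoint()


@pytest.fixture
def sim_psf():
    return PSFSpec(0.1, 0.1)


def make_block(extents=(5.0, 5.0, 3.0), rho=2.0, seed=0,
               size_dist=None, orientation="isotropic3d"):
    """Small synthetic block: centers + geometry + connectivity."""
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = ss.spawn(3)
    vol = VolumeSpec(extents_um=extents, voxel_size_um=(0.05, 0.05, 0.05))
    centers = sample_synapse_centers(vol, rho, np.random.default_rng(s1))
    synapses = sample_synapse_geometry(
        centers, size_dist or SizeDistribution(),
        orientation_model=orientation, seed=np.random.default_rng(s2))
    assign_connectivity(synapses, 64, 16, np.random.default_rng(s3))
    return vol, synapses


def point_synapse(center, area=0.002, normal=(0.0, 0.0, 1.0), sid=0,
                  pre=0, post=0):
    return SynapseDisk(id=sid, center=np.asarray(center, float),
                       normal=np.asarray(normal, float), area=area,
                       pre_neuron=pre, post_neuron=post)
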