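import numpy as np
import pytest

from nucdomains.presets import RemodelerPreset, get_preset
from nucdomains import synthgen as sg


@pytest.fixture
def ino80_nojitter():
    """INO80 signature with jitter off: exact lattice recovery."""
    return RemodelerPreset("ino80", linker_bp=41, nfr_bp=126,
                           spacing_sd_bp=0.0)


@pytest.fixture
def small_config(ino80_nojitter):
    """One 30 kb linear contig, two planted TF sites, no noise."""
    return sg.GeneratorConfig(
        contigs=[("chrS", 30_000, False)],
        tf_sites={"chrS": [10_000, 20_000]},
        preset=ino80_nojitter,
        n_pairs=20_000, n_fragments=20_000,
        frag_len_sd=0.0, midpoint_sd=0.0, seed=7)


@pytest.fixture
def small_gt(small_config):
    return sg.make_ground_truth(small_config)


@pytest.fixture
def ino80_noisy_config():
    """Realistic INO80 chromatin: jitter 5 bp, three TF sites."""
    return sg.GeneratorConfig(
        contigs=[("chrS", 30_000, False)],
        tf_sites={"chrS": [5_000, 15_000, 25_000]},
        preset=get_preset("ino80"),
        n_pairs=100_000, n_fragments=100_000, seed=3)


def brute_force_lattice(sites, length, preset):
    """Independent closed-form dyad lattice for a linear contig.

    Arrays grow outward from each NFR at NRL steps, stopping at the
    midpoint to the neighboring site or 73 bp inside the contig end.
    """
    nrl = 147 + preset.linker_bp
    first = preset.nfr_bp / 2 + 73
    sites = sorted(sites)
    dyads = []
    for i, s in enumerate(sites):
        lim_right = ((sites[i + 1] - s) / 2 if i + 1 < len(sites)
                     else length - 73 - s)
        lim_left = ((s - sites[i - 1]) / 2 if i > 0 else s - 73)
        x = s + first
        while x <= s + lim_right:
            dyads.append(x)
            x += nrl
        x = s - first
        while x >= s - lim_left:
            dyads.append(x)
            x -= nrl
    return np.unique(np.round(dyads).astype(int))
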