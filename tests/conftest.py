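import numpy as np
import pytest

from cilioflow import hydro, transport as tr

#: reference canal geometry / forcing used across the suite
D_CANAL = 8.9e-6
MU = 1e-3
FV = 4000.0


@pytest.fixture(scope="session")
def symmetric_profile():
    """Reference h = d/2 biparabolic profile (fv = 4000 N/m^3, d = 8.9 um)."""
    return hydro.solve_two_region(
        hydro.ModelParams(mu=MU, d=D_CANAL, h=D_CANAL / 2, fv=FV)
    )


@pytest.fixture(scope="session")
def asymmetric_profile():
    """h = d/3 variant exercising the general solver."""
    return hydro.solve_two_region(
        hydro.ModelParams(mu=MU, d=D_CANAL, h=D_CANAL / 3, fv=FV)
    )


@pytest.fixture(scope="session")
def planted_bead_analysis():
    """End-to-end kymograph analysis of one synthetic bead movie.

    Study conditions: planted biparabolic flow with V = 5 um/s in a 8.9 um
    canal, 20 nm beads, 30 s at 10 Hz, 189 nm pixels.  Shared session-wide
    because the analysis chain takes ~15 s.
    """
    from cilioflow import synth, videoflow as vf

    spec = synth.SyntheticSpec(seed=0)
    profile = tr.biparabolic_profile(5e-6, D_CANAL)
    video, truth = synth.make_bead_video(spec, profile)
    m = spec.margin_px
    crop = (m, video.stack.shape[1] - m, 0, video.stack.shape[2])
    events, vprofile, marks = vf.analyze_bead_video(video, crop=crop)
    return {
        "spec": spec,
        "profile": profile,
        "truth": truth,
        "events": events,
        "velocity_profile": vprofile,
        "landmarks": marks,
    }
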