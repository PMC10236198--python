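import numpy as np
import pytest

import venoflow as vf


@pytest.fixture(scope="session")
def blood():
    return vf.BLOOD


@pytest.fixture(scope="session")
def small_cylinder():
    """Coarse straight tube shared by geometry/WSS tests (R=0.25, L=1)."""
    return vf.make_cylinder(0.25, 1.0, 16)


@pytest.fixture(scope="session")
def flat_patch():
    return vf.make_flat_patch(2.0, 2.0, 16)


@pytest.fixture(scope="session")
def table2_record():
    """The echocardiogram worked example: a 4.5-month-old with a high-output
    shunt (HR 138 bpm, EDV 24.27 mL, ESV 9.43 mL, BSA-referenced CO 1334.10
    mL/min)."""
    return vf.EchoRecord(
        heart_rate=138.0, edv=24.27, esv=9.43, bsa=0.37, ref_cardiac_output=1334.10
    )


def constant_series(mesh, vec, phases=(0.0, 0.5), period=1.0):
    """Surface series with the same vector at every node and phase."""
    phases = np.asarray(phases, dtype=float)
    v = np.tile(np.asarray(vec, float), (len(phases), mesh.n_nodes, 1))
    return vf.SurfaceVectorSeries(mesh=mesh, phases=phases, vectors=v, period=period)
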