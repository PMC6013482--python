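import warnings

import numpy as np
import pytest

from confswitch import enm, saxs, synth


def make_sphere_curve(radius=40.0, qmax_rg=0.8, n=120, i0=1e4):
    """Analytic uniform-sphere scattering curve with a 1% sigma channel.

    The q grid stays inside the low-q Guinier regime (qmax·Rg ≈ qmax_rg).
    """
    rg = radius * np.sqrt(3.0 / 5.0)
    q = np.linspace(0.5 * qmax_rg / rg / n * 4, qmax_rg / rg, n)
    qr = q * radius
    inten = (3.0 * (np.sin(qr) - qr * np.cos(qr)) / qr**3) ** 2 * i0
    return saxs.SAXSCurve(q, inten, 0.01 * inten)


def make_sphere_curve_wide(radius=40.0, qmax=0.25, n=150, i0=1e4):
    """Sphere curve over a wide q range (for P(r)/Dmax work)."""
    q = np.linspace(0.005, qmax, n)
    qr = q * radius
    inten = (3.0 * (np.sin(qr) - qr * np.cos(qr)) / qr**3) ** 2 * i0
    return saxs.SAXSCurve(q, inten, 0.01 * np.abs(inten) + 1e-9 * i0)


@pytest.fixture(scope="session")
def sphere_curve():
    return make_sphere_curve()


@pytest.fixture(scope="session")
def sphere_curve_wide():
    return make_sphere_curve_wide()


@pytest.fixture(scope="session")
def dumbbell():
    """The two-lobe closure fixture: 30+30 residues, 5-residue linker, 25 Å apart."""
    return synth.make_two_domain_toy(30, 30, 5, 25.0, seed=1)


@pytest.fixture(scope="session")
def dumbbell_closure(dumbbell):
    """Session-cached eigenvector-tracking run on the dumbbell (~10 s)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return enm.track_closure(dumbbell, "A", "B", max_iterations=400)


@pytest.fixture(scope="session")
def tetramer_scenario(tmp_path_factory):
    """Session-cached tetramer-recovery scenario emission."""
    out = tmp_path_factory.mktemp("tetramer")
    spec = synth.scenario_tetramer_recovery(out, seed=7)
    return out, spec


@pytest.fixture(scope="session")
def tetramer_fit(tetramer_scenario):
    """Session-cached rigid-body fit against the scenario target curve."""
    out, spec = tetramer_scenario
    protomer = synth.make_compact_protomer(n=60, seed=7)
    data = saxs.read_curve(out / "target.dat")
    restraints = saxs.RestraintSpec(residues=tuple(spec.ground_truth["restraint_residues"]))
    fit = saxs.rigid_body_fit(protomer, data, restraints, seed=3, steps=300)
    return protomer, data, restraints, fit


@pytest.fixture(scope="session")
def sv_two_species():
    """Session-cached two-species sedimentation-velocity fit (3.5 S + 8.2 S)."""
    from confswitch import auc

    exp, truth = synth.make_sv([3.5, 8.2], [0.5, 0.5], noise_sd=0.005, seed=42)
    dist = auc.fit_cs(exp, np.linspace(0.5, 15.0, 100), ff0=1.2, alpha=0.1)
    return exp, truth, dist
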