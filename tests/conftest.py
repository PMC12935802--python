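import numpy as np
import pytest

import hawkdove as hd


@pytest.fixture(scope="session")
def baseline_matrix():
    """The resource-contest game used throughout: V=4, C=6."""
    return hd.build_cv_matrix(4.0, 6.0)


@pytest.fixture(scope="session")
def kappa():
    return 0.001


@pytest.fixture(scope="session")
def equilibrium(baseline_matrix, kappa):
    return hd.coexistence_equilibrium(baseline_matrix, kappa)


def measure_local_growth(mode, params, grid, rtol=1e-9, atol=1e-11):
    """Measured exponential growth rate of a zero-flux cosine mode seeded
    along the dominant eigenvector of A(m), fitted over the second half of a
    short horizon (the first half absorbs the non-eigen transient).

    Returns (measured, predicted).  Only meaningful for real dominant
    eigenvalues; callers should select such modes.
    """
    from scipy.fft import dct

    eq = hd.coexistence_equilibrium(params.matrix, params.kappa)
    point = hd.A_matrix(mode, params, grid.length)
    w, vecs = np.linalg.eig(point.matrix)
    i = int(np.argmax(w.real))
    assert abs(w[i].imag) < 1e-12, "test modes must have a real dominant eigenvalue"
    sigma = float(w[i].real)
    vec = vecs[:, i].real
    profile = np.cos(mode * np.pi * grid.x / grid.length)
    amp = 1e-3
    ic = hd.FieldPair(u=eq.u0 + amp * vec[0] * profile, v=eq.v0 + amp * vec[1] * profile)
    horizon = 1.5 if sigma <= 0 else min(1.5, 5.0 / sigma)
    horizon = max(horizon, 0.5 / max(abs(sigma), 0.05))
    res = hd.integrate(
        ic, params, grid, t_end=horizon, steady_tol=None, n_snapshots=7,
        rtol=rtol, atol=atol,
    )
    assert res.status == "completed"

    def coeff(field):
        return abs(dct(field - field.mean(), type=2, norm="ortho")[mode])

    amps = [coeff(u) for u in res.u]
    measured = np.log(amps[-1] / amps[3]) / (res.times[-1] - res.times[3])
    return float(measured), sigma


def measure_nonlocal_growth(mode, params, grid, rtol=1e-9, atol=1e-11):
    """Same measurement for the periodic nonlocal model against B(m)."""
    from scipy.fft import rfft

    eq = hd.coexistence_equilibrium(params.matrix, params.kappa)
    point = hd.B_matrix(mode, params, grid.length)
    w, vecs = np.linalg.eig(point.matrix)
    i = int(np.argmax(w.real))
    assert abs(w[i].imag) < 1e-12, "test modes must have a real dominant eigenvalue"
    sigma = float(w[i].real)
    vec = vecs[:, i].real
    profile = np.cos(2.0 * mode * np.pi * grid.x / grid.length)
    amp = 1e-3
    ic = hd.FieldPair(u=eq.u0 + amp * vec[0] * profile, v=eq.v0 + amp * vec[1] * profile)
    horizon = 1.5 if sigma <= 0 else min(1.5, 5.0 / sigma)
    horizon = max(horizon, 0.5 / max(abs(sigma), 0.05))
    res = hd.integrate_periodic(
        ic, params, grid, t_end=horizon, steady_tol=None, n_snapshots=7,
        rtol=rtol, atol=atol,
    )
    assert res.status == "completed"

    def coeff(field):
        return abs(rfft(field - field.mean())[mode])

    amps = [coeff(u) for u in res.u]
    measured = np.log(amps[-1] / amps[3]) / (res.times[-1] - res.times[3])
    return float(measured), sigma
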