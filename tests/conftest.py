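import numpy as np
import pytest

SEED = 20200417


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


def random_psd(rng, nz, scale=1.0):
    """Random well-conditioned PSD matrix (eigenvalues bounded below)."""
    A = rng.standard_normal((nz, nz))
    return scale * (A @ A.T / nz + 0.2 * np.eye(nz))


def gaussian_renyi_quadrature(Sigma, q):
    """Blind quadrature oracle for the effective volume of N(0, Sigma).

    Integrates the density (scaled by its maximum to avoid underflow at
    large q) over an axis-aligned box wide enough for the q-th power.
    """
    import math

    from scipy import integrate

    Sigma = np.atleast_2d(np.asarray(Sigma, float))
    nz = Sigma.shape[0]
    Sinv = np.linalg.inv(Sigma)
    sign, logdet = np.linalg.slogdet(Sigma)
    log_fmax = -0.5 * (nz * math.log(2 * math.pi) + logdet)

    def scaled(*z):
        z = np.asarray(z)
        return math.exp(-0.5 * q * z @ Sinv @ z)

    widths = 10.0 * np.sqrt(np.diag(Sigma) / q)
    bounds = [(-w, w) for w in widths]
    if abs(q - 1.0) < 1e-12:
        # differential-entropy limit: exp(-int f log f)
        def integrand(*z):
            z = np.asarray(z)
            logf = log_fmax - 0.5 * z @ Sinv @ z
            return -math.exp(logf) * logf

        widths = 12.0 * np.sqrt(np.diag(Sigma))
        val, _ = integrate.nquad(integrand, [(-w, w) for w in widths],
                                 opts={"epsabs": 1e-12, "epsrel": 1e-10})
        return math.exp(val)
    val, _ = integrate.nquad(scaled, bounds,
                             opts={"epsabs": 1e-13, "epsrel": 1e-10})
    # int f^q = fmax^q * val ; Pi_q = (int f^q)^(1/(1-q))
    return math.exp((q * log_fmax + math.log(val)) / (1.0 - q))
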