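import numpy as np
import pytest

from qpidense import OpticalConstants, SyntheticChamberTruth


@pytest.fixture(scope="session")
def constants() -> OpticalConstants:
    return OpticalConstants()


@pytest.fixture(scope="session")
def chamber_truth(constants) -> SyntheticChamberTruth:
    """Self-consistent noiseless chamber truth anchored at Π_c0 = 1.5 MPa."""
    return SyntheticChamberTruth.from_anchor(
        pi_c0_true=1.5,
        ri_at_zero=1.384,
        n_water=constants.n_water,
        chamber_height0=9.2,
        height_slope=0.5,
    )


def between_class_variance(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Independent oracle: per-split between-class variance by direct sums
    (no cumulative shortcuts), −inf where a class would be empty."""
    sb = np.full(len(counts) - 1, -np.inf)
    for t in range(len(counts) - 1):
        w0 = counts[: t + 1].sum()
        w1 = counts[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        sb[t] = w0 * w1 * (mu0 - mu1) ** 2
    return sb


def brute_force_otsu(counts: np.ndarray, centers: np.ndarray) -> float:
    """Exhaustive-search Otsu threshold (lowest maximiser's bin centre)."""
    return float(centers[int(np.argmax(between_class_variance(counts, centers)))])


def assert_attains_max_variance(img: np.ndarray, threshold: float, rel_tol: float = 1e-9):
    """The given threshold must achieve the exhaustive-search maximum of the
    between-class variance on the 256-bin histogram (ties allowed)."""
    counts, edges = np.histogram(img, 256, (img.min(), img.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sb = between_class_variance(counts, centers)
    t = int(np.argmin(np.abs(centers[:-1] - threshold)))
    assert sb[t] >= sb.max() * (1.0 - rel_tol), (
        f"threshold {threshold} attains {sb[t]}, exhaustive max is {sb.max()}"
    )
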