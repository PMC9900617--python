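import numpy as np
import pytest

from aaamotion.geometry import Centerline, VesselModel
from aaamotion.registration import CorrespondenceSet, LinearTransform


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_affine(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random invertible matrix with |det| in [0.5, 2] and ||t|| <= 50 mm."""
    while True:
        A = rng.uniform(-1.5, 1.5, (3, 3)) + np.eye(3)
        det = np.linalg.det(A)
        if 0.5 <= abs(det) <= 2.0:
            break
    t = rng.uniform(-1, 1, 3)
    t = t / np.linalg.norm(t) * rng.uniform(0, 50)
    return A, t


def landmark_cloud(rng: np.random.Generator, n: int = 9) -> np.ndarray:
    """Well-spread non-coplanar source points on a ~100 mm scale."""
    while True:
        pts = rng.uniform(-60, 60, (n, 3))
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[2] > 5.0:  # comfortably 3-D
            return pts


def make_correspondences(
    src: np.ndarray,
    A: np.ndarray,
    t: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    validation_src: np.ndarray | None = None,
    maxpoints: list | None = None,
) -> CorrespondenceSet:
    """Build a CorrespondenceSet by pushing src through p ↦ A p + t."""
    dst = src @ A.T + t
    if noise_sd > 0:
        dst = dst + rng.normal(0, noise_sd, dst.shape)
    labels = [f"lm_{i}" for i in range(len(src))]
    fit = tuple((s, d, lab) for s, d, lab in zip(src, dst, labels))
    val = None
    if validation_src is not None:
        vt = A @ validation_src + t
        if noise_sd > 0:
            vt = vt + rng.normal(0, noise_sd, 3)
        val = (validation_src, vt, "validation")
    mp = tuple(maxpoints) if maxpoints else ()
    return CorrespondenceSet("T01", fit, val, mp)


def straight_tube(radius: float = 10.0, length: float = 100.0, n: int = 101) -> VesselModel:
    z = np.linspace(0, length, n)
    pts = np.column_stack([np.zeros(n), np.zeros(n), -z])
    c = Centerline(pts, {"lowest_renal": 0, "aortic_bifurcation": n - 1})
    r = np.full(n, radius)
    return VesselModel(c, r, r.copy())


# --- independent oracles -----------------------------------------------------


def procrustes_oracle(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid fit via scipy's orthogonal Procrustes, independent of the package."""
    from scipy.spatial.transform import Rotation

    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - mu_d, src - mu_s)
    R = rot.as_matrix()
    return R, mu_d - R @ mu_s


def affine_normal_equations_oracle(src: np.ndarray, dst: np.ndarray):
    """Affine fit by explicitly forming and solving the normal equations."""
    X = np.hstack([src, np.ones((len(src), 1))])
    beta = np.linalg.solve(X.T @ X, X.T @ dst)
    return beta[:3].T, beta[3]
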