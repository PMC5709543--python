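import numpy as np
import pytest

from condylometry.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One rendered phantom pair with truth, shared across the session."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free phantom with the soft envelope collapsed.

    With partial-volume rendering against an air background, the
    intensity 600 contour coincides exactly with the center-in-solid
    label grid, enabling bit-exact voxel-count checks.
    """
    spec = PhantomSpec(
        seed=0, noise_sd=0.0, blur_sigma=0.0, soft_semiaxes=(1e-6, 1e-6, 1e-6)
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_case_files(tmp_path_factory):
    """Phantom pair written to disk as pipeline inputs (volumes + landmarks)."""
    from condylometry import volume_io
    from condylometry.pipeline import save_landmarks

    spec = PhantomSpec(seed=3)
    pre, post, truth = generate_phantom(spec)
    base = tmp_path_factory.mktemp("phantom_case")
    volume_io.write_volume(pre, str(base / "pre.nii"))
    volume_io.write_volume(post, str(base / "post.nii"))
    save_landmarks(truth.landmarks_pre, str(base / "pre_landmarks.json"))
    save_landmarks(truth.landmarks_post, str(base / "post_landmarks.json"))
    return {
        "dir": base,
        "spec": spec,
        "truth": truth,
        "pre_volume": str(base / "pre.nii"),
        "post_volume": str(base / "post.nii"),
        "pre_landmarks": str(base / "pre_landmarks.json"),
        "post_landmarks": str(base / "post_landmarks.json"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
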