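import numpy as np
import pytest

from wims import detect
from wims.synthdata import detection_scene, scenario_library, simulate_movie

DETECTION_SEED = 1
FIG5_SCALES = tuple(range(4, 21))
FIG5_XIS = (0.5, 1.0, 1.5)
N_THETAS = 180


@pytest.fixture(scope="session")
def detection_scene_result():
    """One 20-adhesion SNR-10 frame, detected once with the survey grids.

    Shared between unit and acceptance tests because the full-grid
    transform is the most expensive single computation in the suite.
    """
    cfg = detection_scene(n_adhesions=20, snr=10.0, seed=DETECTION_SEED)
    series, truth = simulate_movie(cfg)
    adhesions = detect.detect_adhesions(
        series.frame(0),
        scales=FIG5_SCALES,
        xis=FIG5_XIS,
        thetas=N_THETAS,
        threshold_fraction=0.10,
    )
    return {"series": series, "truth": truth, "adhesions": adhesions, "config": cfg}


@pytest.fixture(scope="session")
def scenarios():
    return scenario_library(seed=DETECTION_SEED)


def match_detections(adhesions, truth_table, radius=2.0):
    """Greedy one-to-one matching of detections to ground truth."""
    used = set()
    matches = []
    for _, row in truth_table.iterrows():
        best = None
        for i, ad in enumerate(adhesions):
            if i in used:
                continue
            d = np.hypot(ad.x - row.x, ad.y - row.y)
            if best is None or d < best[0]:
                best = (d, i)
        if best is not None and best[0] <= radius:
            used.add(best[1])
            matches.append((best[0], adhesions[best[1]], row))
    return matches, used
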