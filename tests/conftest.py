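import numpy as np
import pytest

from pswtrial.simulate import ClassLabel, ScaleDefinition, SubjectTrajectory


def allocate_total(total: int, scale: ScaleDefinition) -> np.ndarray:
    """Deterministically spread an integer total over the scale items."""
    items = np.zeros(scale.n_items, dtype=int)
    remaining = int(total)
    while remaining > 0:
        moved = False
        for i in range(scale.n_items):
            if remaining == 0:
                break
            if items[i] < scale.item_max[i]:
                items[i] += 1
                remaining -= 1
                moved = True
        if not moved:
            raise ValueError(f"total {total} exceeds the scale maximum")
    return items


def subject_from_totals(
    sid: str,
    arm: str,
    totals: dict[float, int],
    scale: ScaleDefinition,
    latent: ClassLabel = ClassLabel.DminusPminus,
) -> SubjectTrajectory:
    """Build a trajectory whose per-visit totals are exactly as requested."""
    return SubjectTrajectory(
        subject_id=sid,
        arm=arm,
        latent_class=latent,
        item_scores={w: allocate_total(t, scale) for w, t in totals.items()},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
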