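import numpy as np
import pytest

from vlsm import (
    ClinicalRecord,
    FrequencyCategory,
    Hemisphere,
    LesionVolume,
    Lobe,
    Pathology,
    Resection,
    SeizureType,
    TemplateGrid,
)

_SCORE_TO_CAT = {
    0: FrequencyCategory.NONE,
    1: FrequencyCategory.RARE_1_2,
    2: FrequencyCategory.MONTHLY,
    3: FrequencyCategory.WEEKLY,
    4: FrequencyCategory.DAILY,
}


def make_record(subject_id="s1", score=0, age=40.0, sex=1, volume=50.0, **kw):
    """A valid clinical record with sensible defaults for tests."""
    cat = _SCORE_TO_CAT[score]
    stype = kw.pop("seizure_type", SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC)
    if score == 0:
        stype = SeizureType.NONE
    defaults = dict(
        asm_use=score > 0,
        resection=Resection.PARTIAL,
        pathology=Pathology.ASTROCYTOMA,
        hemisphere=Hemisphere.LEFT,
        lobes=frozenset({Lobe.FRONTAL}),
        engel_class=None,
    )
    defaults.update(kw)
    return ClinicalRecord(
        subject_id=subject_id, age=age, sex=sex, tumor_volume=volume,
        frequency_category=cat, seizure_type=stype, **defaults,
    )


@pytest.fixture
def small_grid():
    return TemplateGrid((6, 5, 4), (2.0, 2.0, 2.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masks(grid, n, rng, p=0.4):
    """Random binary lesion volumes, each guaranteed non-empty."""
    masks = []
    for i in range(n):
        data = (rng.random(grid.dims) < p).astype(np.uint8)
        data.ravel()[rng.integers(grid.n_voxels)] = 1
        masks.append(LesionVolume(f"s{i}", data, grid))
    return masks


def _group(n, score_of, n_gross, n_asm, n_left, n_frontal, n_age40, n_male,
           types=None, prefix="g"):
    """Records matching per-variable marginal counts within one group.

    Attributes are assigned independently by index, which reproduces any
    per-variable 2x2 group table exactly (joint structure is irrelevant
    to those tables).
    """
    recs = []
    for i in range(n):
        score = score_of(i)
        if score == 0:
            stype = SeizureType.NONE
        elif types is not None:
            stype = types[i]
        else:
            stype = SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC
        recs.append(make_record(
            subject_id=f"{prefix}{i:03d}",
            score=score,
            age=55.0 if i < n_age40 else 30.0,
            sex=1 if i < n_male else 0,
            volume=80.0,
            seizure_type=stype,
            asm_use=i < n_asm,
            resection=Resection.GROSS_TOTAL if i < n_gross else Resection.PARTIAL,
            hemisphere=Hemisphere.LEFT if i < n_left else Hemisphere.RIGHT,
            lobes=frozenset({Lobe.FRONTAL}) if i < n_frontal else frozenset({Lobe.TEMPORAL}),
        ))
    return recs


@pytest.fixture(scope="session")
def printed_cohort():
    """A 352-subject cohort reconstructed from printed per-variable counts.

    126 frequent (75 monthly + 25 weekly + 26 daily), 120 non-frequent
    (1-2 lifetime seizures) and 106 seizure-free subjects, with each
    clinical variable matching its printed group counts.
    """
    def freq_score(i):  # 75 monthly, 25 weekly, 26 daily
        return 2 if i < 75 else (3 if i < 100 else 4)

    types_freq = (
        [SeizureType.FOCAL_AWARE] * 40
        + [SeizureType.FOCAL_IMPAIRED_AWARENESS] * 15
        + [SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC] * 71
    )
    types_nonfreq = (
        [SeizureType.FOCAL_AWARE] * 12
        + [SeizureType.FOCAL_IMPAIRED_AWARENESS] * 11
        + [SeizureType.FOCAL_TO_BILATERAL_TONIC_CLONIC] * 97
    )
    frequent = _group(
        126, freq_score, n_gross=46, n_asm=126, n_left=72, n_frontal=89,
        n_age40=43, n_male=83, types=types_freq, prefix="f",
    )
    nonfrequent = _group(
        120, lambda i: 1, n_gross=64, n_asm=113, n_left=73, n_frontal=89,
        n_age40=43, n_male=71, types=types_nonfreq, prefix="n",
    )
    none = _group(
        106, lambda i: 0, n_gross=55, n_asm=31, n_left=45, n_frontal=60,
        n_age40=48, n_male=58, prefix="z",
    )
    return frequent + nonfrequent + none
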