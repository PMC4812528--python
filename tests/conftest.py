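import numpy as np
import pytest

from pathrisk.cohort import SampleAnnotation


def make_annotations(strata, cohort="utah", prefix="S"):
    """Build annotations from (n, family_history, brca_status, cancer) strata."""
    out = []
    i = 0
    for n, fh, brca, cancer in strata:
        for _ in range(n):
            out.append(
                SampleAnnotation(
                    sample_id=f"{prefix}{i:03d}",
                    cohort=cohort,
                    family_history=fh,
                    brca_status=brca,
                    developed_cancer=cancer,
                )
            )
            i += 1
    return out


# composition of the two source cohorts (family history, BRCA1/2, cancer)
UTAH_STRATA = [
    (16, True, "carrier", True),
    (23, True, "BRCAX", True),
    (18, True, "carrier", False),
    (26, True, "BRCAX", False),
    (22, False, "none", True),
    (19, False, "none", False),
]
ONTARIO_STRATA = [
    (11, True, "carrier", True),
    (17, True, "BRCAX", True),
    (14, True, "carrier", False),
    (18, True, "BRCAX", False),
    (8, False, "none", True),
    (5, False, "none", False),
]


@pytest.fixture
def utah_annotations():
    return make_annotations(UTAH_STRATA, "utah", "U")


@pytest.fixture
def ontario_annotations():
    return make_annotations(ONTARIO_STRATA, "ontario", "O")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "PW1\tfirst pathway\tA\tB\tC\n"
        "PW2\tsecond pathway\tA\tA\tb\n"
        "PW3\tthird pathway\tD\tE\tF\tG\tH\tI\n"
    )
    return path
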