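import math

import pytest
from hypothesis import HealthCheck, settings

from ssfe.alignment import SubstitutionMatrix, blosum62
from ssfe.pocket import ReferenceAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def matrix() -> SubstitutionMatrix:
    return blosum62()


@pytest.fixture(scope="session")
def annotation() -> ReferenceAnnotation:
    return ReferenceAnnotation.default()


@pytest.fixture(scope="session")
def identity_matrix() -> SubstitutionMatrix:
    return SubstitutionMatrix.identity("ACDEFGHIKLMNPQRSTVWYX", match=1.0, mismatch=0.0)


def brute_force_global_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Exhaustive enumeration of all global alignments (affine gap model).

    Independent oracle for the DP implementation: walks every monotone
    alignment path, charging gap_open for the first residue of a gap run
    and gap_extend for each continuation.
    """
    best = -math.inf
    la, lb = len(a), len(b)

    def rec(i: int, j: int, state: int, score: float) -> None:
        nonlocal best
        if i == la and j == lb:
            best = max(best, score)
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, 0, score + matrix.score(a[i], b[j]))
        if i < la:
            rec(i + 1, j, 1, score - (gap_extend if state == 1 else gap_open))
        if j < lb:
            rec(i, j + 1, 2, score - (gap_extend if state == 2 else gap_open))

    rec(0, 0, -1, 0.0)
    return best
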