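import pytest

from ladderpath import parse_pom
from ladderpath.synthetic import example_paths, worked_examples

JX1_TEXT = "{A, B, C, D, E, F // CD, EF // BCD(2)}"
JX2_TEXT = "{A, B(2), C(3), D(3), E, F // DBC, EF}"
JX0_TEXT = "{A, B(3), C(4), D(4), E(2), F(2)}"
JQ_TEXT = "{A, B(2), C, D(2), E // AB, ED(4) // ABD(2), CAB // ABDED // ABDEDBED}"
JYP_TEXT = "{BCD, EF(3), H(2), K(2), MU(2), R(2), T(2) // BCDEF, TEF}"


@pytest.fixture(scope="session")
def fixtures():
    return worked_examples()


@pytest.fixture(scope="session")
def paths():
    return example_paths()


@pytest.fixture
def jx1(fixtures):
    fx = fixtures["X"]
    return parse_pom(JX1_TEXT, fx.basic, fx.target)


@pytest.fixture
def jx2(fixtures):
    fx = fixtures["X"]
    return parse_pom(JX2_TEXT, fx.basic, fx.target)


@pytest.fixture
def jx0(fixtures):
    fx = fixtures["X"]
    return parse_pom(JX0_TEXT, fx.basic, fx.target)


@pytest.fixture
def jq(fixtures):
    fx = fixtures["Q"]
    return parse_pom(JQ_TEXT, fx.basic, fx.target)
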