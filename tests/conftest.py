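import pytest
from hypothesis import HealthCheck, settings

from micropattern import AssociationRecord, AssociationTable, Category, MicrobeSet, SetDatabase

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def small_db() -> SetDatabase:
    """Six microbes in three overlapping sets (two disease, one position)."""
    return SetDatabase(
        [
            MicrobeSet("cirrhosis", Category.DISEASE,
                       frozenset({"veillonella parvula", "streptococcus oralis", "prevotella copri"})),
            MicrobeSet("colitis", Category.DISEASE,
                       frozenset({"prevotella copri", "roseburia faecis"})),
            MicrobeSet("gut", Category.POSITION,
                       frozenset({"veillonella parvula", "roseburia faecis",
                                  "bacteroides fragilis", "akkermansia muciniphila"})),
        ]
    )


@pytest.fixture
def small_table() -> AssociationTable:
    """Four diseases, concordant repeats, one microbe shared by all diseases."""
    rows = [
        ("ibd", "roseburia faecis", -1),
        ("ibd", "roseburia faecis", -1),
        ("ibd", "escherichia coli", 1),
        ("t2d", "roseburia faecis", -1),
        ("t2d", "akkermansia muciniphila", -1),
        ("obesity", "akkermansia muciniphila", -1),
        ("obesity", "prevotella copri", 1),
        ("cirrhosis", "veillonella parvula", 1),
        ("cirrhosis", "prevotella copri", -1),
    ]
    # make one microbe ubiquitous so its idf weight is exactly zero
    rows += [(d, "bacteroides vulgatus", 1) for d in ("ibd", "t2d", "obesity", "cirrhosis")]
    return AssociationTable(AssociationRecord(d, m, e) for d, m, e in rows)
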