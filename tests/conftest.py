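import pytest

from fossilcomp.characters import CharacterContributionTable, ElementPartKey


@pytest.fixture
def worked_example_table() -> CharacterContributionTable:
    """655-character table with a 7-character maxilla and a 17-character femur.

    17/655 = 2.595...% rounds to the published femur share of 2.6%; the
    remaining characters sit on a filler key so the table total is exact.
    """
    maxilla = ElementPartKey("maxilla")
    femur = ElementPartKey("femur")
    rest = ElementPartKey("braincase")
    return CharacterContributionTable(
        total_characters=655,
        entries={maxilla: 7, femur: 17, rest: 631},
        region={maxilla: "skull", femur: "hindlimbs", rest: "skull"},
    )


@pytest.fixture
def three_stage_boundaries():
    """Three contiguous stages, old to young."""
    return [
        ("Tithonian", 150.8, 145.5),
        ("Berriasian", 145.5, 140.2),
        ("Valanginian", 140.2, 136.4),
    ]
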