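"""Game classification and grid scans."""

import numpy as np
import pytest

import fluxgames as fg
from fluxgames.errors import InputError
from fluxgames.fixtures import harmony, prisoners_dilemma, snowdrift
from fluxgames.landscape import profile_region


def classify(tensor, producer="C", nonproducer="D"):
    return fg.classify_game(
        fg.find_nash_ilp(tensor), tensor, producer, nonproducer
    ).label


def test_canonical_matrices_classified():
    assert classify(prisoners_dilemma()) == "prisoners_dilemma"
    assert classify(snowdrift()) == "snowdrift"
    assert classify(harmony()) == "mutually_beneficial"


def test_all_dead_is_non_viable():
    d = fg.DEFAULT_DEATH_RATE
    t = fg.bimatrix([[d, d], [d, d]])
    assert classify(t) == "non_viable"


def test_producer_dominance_when_cheater_never_survives():
    d = fg.DEFAULT_DEATH_RATE
    # non-producer dead against everything, producer viable only in self-play
    t = fg.bimatrix([[2.0, d], [d, d]])
    assert classify(t) == "producer_dominance"
    # if the producer also survives the cheater, the game is mutually beneficial
    assert classify(fg.bimatrix([[2.0, 1.0], [d, d]])) == "mutually_beneficial"


def ordering_lookup(a_cc, a_cd, a_dc, a_dd):
    """Independent canonical-ordering table for distinct payoffs."""
    if a_dc > a_cc and a_cd > a_dd:
        return "snowdrift"
    if a_cc > a_dc and a_cd > a_dd:
        return "mutually_beneficial"
    if a_dc > a_cc and a_dd > a_cd and a_cc > a_dd:
        return "prisoners_dilemma"
    return None  # orderings outside the three named classes


def test_classification_agrees_with_ordering_lookup_on_random_matrices(rng):
    checked = 0
    for _ in range(1000):
        vals = np.round(rng.uniform(0.1, 10.0, size=4), 6)
        if len(set(vals)) < 4:
            continue
        a_cc, a_cd, a_dc, a_dd = vals
        t = fg.bimatrix([[a_cc, a_cd], [a_dc, a_dd]])
        expected = ordering_lookup(a_cc, a_cd, a_dc, a_dd)
        got = classify(t)
        if expected is None:
            assert got in ("producer_dominance", "other")
        else:
            assert got == expected
            checked += 1
    assert checked > 500


def test_one_by_one_grid_equals_direct_classification():
    factory = fg.sucrose_scan_factory()
    ax1 = fg.AxisSpec("atp_cost_x", [1.0])
    ax2 = fg.AxisSpec("capture_efficiency_e", [0.4])
    landscape = fg.scan(factory, ax1, ax2)
    cell = landscape.cells[(0, 0)]
    direct = factory(atp_cost_x=1.0, capture_efficiency_e=0.4).build_tensor()
    assert cell.tensor.entries == direct.entries
    assert cell.game_class.label == classify(direct, "WT", "MT")


def test_scan_is_deterministic():
    factory = fg.amino_scan_factory()
    ax = fg.AxisSpec("leakiness_A", [0.0, 50.0])
    ay = fg.AxisSpec("leakiness_B", [25.0, 75.0])
    l1 = fg.scan(factory, ax, ay)
    l2 = fg.scan(factory, ax, ay)
    assert l1.to_dataframe().equals(l2.to_dataframe())


def test_sustainable_region_downward_closed():
    landscape = fg.scan(
        fg.amino_scan_factory(),
        fg.leakiness_axis("leakiness_A", 6),
        fg.leakiness_axis("leakiness_B", 6),
    )
    sus = fg.sustainable_region(landscape)
    assert sus[0, 0]  # zero leakiness always sustainable
    assert not sus[-1, -1]  # full leakiness on both axes collapses the producer
    # reducing either leakiness from a sustainable cell stays sustainable
    for i in range(6):
        for j in range(6):
            if sus[i, j]:
                assert i == 0 or sus[i - 1, j]
                assert j == 0 or sus[i, j - 1]


def test_profile_region_distinguishes_viable_nash(amino_tensor):
    landscape = fg.scan(
        fg.amino_scan_factory(),
        fg.AxisSpec("leakiness_A", [40.0, 60.0]),
        fg.AxisSpec("leakiness_B", [40.0, 60.0]),
    )
    viable = profile_region(landscape, ("01", "10"), viable_only=True)
    any_nash = profile_region(landscape, ("01", "10"), viable_only=False)
    assert np.all(any_nash >= viable)
    assert viable[0, 0]  # cross-feeding viable at moderate equal leakiness


def test_landscape_tsv_round_trip_columns(tmp_path):
    landscape = fg.scan(
        fg.sucrose_scan_factory(),
        fg.AxisSpec("atp_cost_x", [0.5, 1.5]),
        fg.AxisSpec("capture_efficiency_e", [0.2, 0.8]),
    )
    path = tmp_path / "landscape.tsv"
    landscape.to_tsv(path)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    assert list(df.columns) == [
        "atp_cost_x",
        "capture_efficiency_e",
        "game_class",
        "nash_profiles",
        "viable_nash_profiles",
        "producer_viable",
    ]
    assert len(df) == 4


# --------------------------------------------------------------------- #
# amino acid pair enumeration
# --------------------------------------------------------------------- #
def test_three_items_three_pairs():
    assert fg.enumerate_amino_acid_pairs(["a", "b", "c"]) == [
        ("a", "b"), ("a", "c"), ("b", "c"),
    ]


def test_twenty_amino_acids_one_exclusion_gives_189():
    pairs = fg.enumerate_amino_acid_pairs(fg.AMINO_ACIDS, fg.EXCLUDED_PAIRS)
    assert len(pairs) == 189
    assert ("Ala", "Ile") not in pairs


def test_duplicate_names_rejected():
    with pytest.raises(InputError, match="duplicate"):
        fg.enumerate_amino_acid_pairs(["a", "a", "b"])


def test_unknown_exclusion_rejected():
    with pytest.raises(InputError, match="exclusions"):
        fg.enumerate_amino_acid_pairs(["a", "b"], [("a", "z")])
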