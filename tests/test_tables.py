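import numpy as np
import pytest

from mivmsim.tables import TABLE_NAMES, get_printed, get_table


@pytest.mark.parametrize("name", TABLE_NAMES)
def test_counts_are_consistent(name):
    t = get_table(name)
    assert np.all(t.counts >= 0)
    assert t.counts.shape == (len(t.groups), len(t.categories))
    # evaluated n per group equals the row sum by construction
    assert np.array_equal(t.n_evaluated, t.counts.sum(axis=1))


def test_published_sample_sizes():
    assert get_table("nuclear_native").n_evaluated.tolist() == [75, 75, 72]
    assert get_table("nuclear_supports").n_evaluated.tolist() == [144, 59, 69, 76]
    assert get_table("nuclear_alginate").n_evaluated.tolist() == [74, 72]
    assert get_table("mito_alginate").n_evaluated.tolist() == [37, 34]


@pytest.mark.parametrize("name", TABLE_NAMES)
def test_printed_metadata_aligns_with_counts(name):
    t = get_table(name)
    printed = get_printed(name)
    assert np.asarray(printed["printed_percent"]).shape == t.counts.shape
    assert printed["control"] in t.groups
    for g, grades in printed["printed_grades"].items():
        assert g in t.groups and g != printed["control"]
        assert len(grades) == len(t.categories)
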