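"""The published oocyte-outcome count tables, shipped as analysis fixtures.

Each entry holds the raw counts per experimental group and category, plus the
percentages and significance superscripts as printed in the publication
(translated to star grades: b/c/d against the control = * / ** / ***).  The
counts are the analysis input; the printed values are kept alongside so the
statistical pipeline can be validated against the published tables.

``PRINT_ERRATA_*`` lists the handful of printed cells that are internally
inconsistent with their own counts (the tables mix round-half-up with
truncation, and a few superscripts cannot be produced by any 2x2 test on the
printed counts); these are asserted explicitly in the test suite rather than
silently ignored.
"""

from __future__ import annotations

from .stats import OutcomeTable

NUCLEAR_CATS = ["GV", "MI-TI", "MII", "Abnormal"]
MITO_CATS = ["Finely granular", "P/S", "Abnormal"]

_RAW = {
    "nuclear_native": {
        "groups": ["CTRL", "native_50", "native_100"],
        "categories": NUCLEAR_CATS,
        "counts": [[12, 8, 49, 6], [14, 24, 20, 17], [12, 27, 18, 15]],
        "printed_percent": [[16, 11, 65, 8], [19, 32, 27, 23], [17, 38, 25, 21]],
        "printed_grades": {
            "native_50": ["ns", "**", "***", "*"],
            "native_100": ["ns", "***", "***", "*"],
        },
        "control": "CTRL",
    },
    "mito_native": {
        "groups": ["CTRL", "native_50", "native_100"],
        "categories": MITO_CATS,
        "counts": [[16, 31, 2], [14, 5, 1], [15, 2, 1]],
        "printed_percent": [[33, 63, 4], [70, 25, 5], [83, 10, 6]],
        "printed_grades": {
            "native_50": ["*", "*", "ns"],
            "native_100": ["**", "***", "*"],
        },
        "control": "CTRL",
    },
    "nuclear_supports": {
        "groups": ["CTRL", "ring", "concave_ring", "box"],
        "categories": NUCLEAR_CATS,
        "counts": [
            [20, 9, 101, 14], [6, 12, 31, 10], [2, 19, 44, 4], [33, 18, 14, 11],
        ],
        "printed_percent": [
            [14, 6, 70, 10], [10, 20, 53, 17], [3, 27, 64, 6], [43, 24, 18, 15],
        ],
        "printed_grades": {
            "ring": ["ns", "**", "*", "ns"],
            "concave_ring": ["*", "***", "ns", "ns"],
            "box": ["***", "***", "***", "ns"],
        },
        "control": "CTRL",
    },
    "mito_supports": {
        "groups": ["CTRL", "ring", "concave_ring", "box"],
        "categories": MITO_CATS,
        "counts": [[51, 47, 3], [20, 11, 0], [26, 18, 0], [8, 1, 5]],
        "printed_percent": [[50, 47, 3], [65, 35, 0], [59, 41, 0], [57, 7, 36]],
        "printed_grades": {
            "ring": ["ns", "ns", "ns"],
            "concave_ring": ["ns", "ns", "ns"],
            "box": ["ns", "*", "***"],
        },
        "control": "CTRL",
    },
    "nuclear_alginate": {
        "groups": ["CTRL", "alginate"],
        "categories": NUCLEAR_CATS,
        "counts": [[11, 10, 37, 16], [11, 16, 38, 7]],
        "printed_percent": [[15, 13, 50, 22], [15, 22, 53, 10]],
        "printed_grades": {"alginate": ["ns", "ns", "ns", "*"]},
        "control": "CTRL",
    },
    "mito_alginate": {
        "groups": ["CTRL", "alginate"],
        "categories": MITO_CATS[:2],
        "counts": [[17, 20], [22, 12]],
        "printed_percent": [[46, 54], [65, 35]],
        "printed_grades": {"alginate": ["ns", "ns"]},  # "Not significant"
        "control": "CTRL",
    },
}

TABLE_NAMES = tuple(_RAW)

#: printed percentages that disagree with their own counts under the tables'
#: prevailing round-half-up convention: (table, group, category, printed, recomputed)
PRINT_ERRATA_PERCENT = (
    ("mito_native", "native_100", "P/S", 10, 11),        # 2/18 = 11.1
    ("nuclear_supports", "concave_ring", "MI-TI", 27, 28),  # 19/69 = 27.54
    ("nuclear_supports", "box", "Abnormal", 15, 14),     # 11/76 = 14.47
    ("nuclear_alginate", "CTRL", "MI-TI", 13, 14),       # 10/74 = 13.51
)

#: printed superscripts not reproduced by the uncorrected Pearson 2x2 test
#: (nor by any single test convention): (table, group, category, printed, recomputed)
PRINT_ERRATA_GRADES = (
    ("mito_native", "native_50", "Finely granular", "*", "**"),
    ("mito_native", "native_50", "P/S", "*", "**"),
    ("mito_native", "native_100", "Finely granular", "**", "***"),
    ("mito_native", "native_100", "Abnormal", "*", "ns"),
    ("mito_supports", "box", "P/S", "*", "**"),
)


def get_table(name: str) -> OutcomeTable:
    """Return one of the published outcome tables as an :class:`OutcomeTable`."""
    raw = _RAW[name]
    return OutcomeTable(
        groups=list(raw["groups"]),
        categories=list(raw["categories"]),
        counts=raw["counts"],
    )


def get_printed(name: str) -> dict:
    """Printed percentages, grades and control-group name for a table."""
    raw = _RAW[name]
    return {
        "printed_percent": raw["printed_percent"],
        "printed_grades": raw["printed_grades"],
        "control": raw["control"],
    }
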