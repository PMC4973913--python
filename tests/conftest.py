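import pandas as pd
import pytest
from hypothesis import settings

from surfaceome import AnnotationMap, ProteinTable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_table(rows, experiments=("e1", "e2")):
    """Build a ProteinTable from (acc, length, pn, sc, mq-list, lfq-list, flags)."""
    recs = []
    for acc, length, pn, sc, mq, lfq, flags in rows:
        rec = {
            "accession": acc,
            "description": "",
            "length": length,
            "pn": pn,
            "sc": sc,
            "flags": flags,
        }
        rec.update({f"mq:{e}": v for e, v in zip(experiments, mq)})
        rec.update({f"lfq:{e}": v for e, v in zip(experiments, lfq)})
        recs.append(rec)
    return ProteinTable(pd.DataFrame(recs))


@pytest.fixture
def small_table():
    return make_table(
        [
            ("P1", 100, 5, 10, [1e9, 2e9], [1e9, 2e9], ""),
            ("P2", 200, 3, 5, [5e8, 0.0], [5e8, 0.0], ""),
            ("P3", 50, 1, 1, [1e7, 1e7], [1e7, 1e7], ""),
        ]
    )


@pytest.fixture
def flagged_table():
    return make_table(
        [
            ("P1", 100, 5, 10, [1e9, 2e9], [1e9, 2e9], ""),
            ("P2", 200, 3, 5, [5e8, 6e8], [5e8, 6e8], "contaminant"),
            ("P3", 50, 1, 1, [1e7, 1e7], [1e7, 1e7], ""),
            ("P4", 80, 2, 2, [2e7, 3e7], [2e7, 3e7], "reverse;contaminant"),
            ("P5", 120, 4, 6, [4e8, 5e8], [4e8, 5e8], ""),
        ]
    )


@pytest.fixture
def feature_annotations():
    return AnnotationMap(
        features={
            "P1": frozenset({"GA", "PM"}),
            "P2": frozenset({"TM", "PM"}),
            "P3": frozenset({"SP", "ECM"}),
            "P4": frozenset({"TM"}),
            "P5": frozenset(),
        }
    )
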