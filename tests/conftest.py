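import json

import numpy as np
import pytest

from otufs.io import AbundanceTable


def make_biom_json(counts, feature_ids, sample_ids, *, matrix_type="dense",
                   taxonomy=None, sample_metadata=None):
    """Build a BIOM 1.0 JSON document as a dict."""
    counts = np.asarray(counts)
    k, m = counts.shape
    if matrix_type == "dense":
        data = counts.tolist()
    else:
        rr, cc = np.nonzero(counts)
        data = [[int(r), int(c), float(counts[r, c])] for r, c in zip(rr, cc)]
    rows = []
    for i, fid in enumerate(feature_ids):
        meta = None
        if taxonomy is not None and taxonomy[i]:
            meta = {"taxonomy": taxonomy[i]}
        rows.append({"id": fid, "metadata": meta})
    columns = []
    for i, sid in enumerate(sample_ids):
        meta = None
        if sample_metadata is not None:
            meta = sample_metadata[i]
        columns.append({"id": sid, "metadata": meta})
    return {
        "id": "fixture",
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "tests",
        "date": "",
        "matrix_type": matrix_type,
        "matrix_element_type": "int",
        "shape": [k, m],
        "data": data,
        "rows": rows,
        "columns": columns,
    }


@pytest.fixture
def write_biom_json(tmp_path):
    def _write(name, **kwargs):
        path = tmp_path / name
        path.write_text(json.dumps(make_biom_json(**kwargs)))
        return str(path)

    return _write


@pytest.fixture
def toy_table():
    """3 features x 4 samples with hand-set counts and taxonomy."""
    return AbundanceTable(
        counts=np.array([[1, 0, 2, 3], [2, 3, 0, 1], [0, 5, 5, 0]]),
        feature_ids=["f1", "f2", "f3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        taxonomy=["k__A; g__x", "k__B; g__y", ""],
    )
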