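import numpy as np
import pytest
from hypothesis import settings

from mowoats import ExpressionMatrix

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

# The published human-fibroblasts-serum excerpt: 7 genes, the six printed
# time points (t = 0, 15 min, 30 min, 1 h, 2 h, 24 h).
TABLE1_ROWS = {
    "W95908": [1.5962, 0.534, -1.8179, -0.035017, 1.8996, -0.22469],
    "AA045003": [0.095122, 2.0874, 0.26687, 0.61037, 0.85082, -0.76362],
    "AA044434": [0.84243, 1.359, 0.68745, 0.84243, 0.32584, -1.9471],
    "W88572": [1.1363, 0.98137, 1.1363, 0.36156, 0.30991, -0.67147],
    "AA059077": [0.23452, 1.6489, 1.6175, 0.61169, 0.54883, -1.777],
    "AA035657": [0.64514, 1.2043, 1.0179, 0.64514, 0.94334, -1.6286],
    "AA180272": [0.28406, 1.3116, 1.408, 0.70151, 0.28406, -1.5463],
}
TABLE1_FEATURES = ["t0h", "t15m", "t30m", "t1h", "t2h", "t24h"]


@pytest.fixture
def serum_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        tuple(TABLE1_ROWS),
        tuple(TABLE1_FEATURES),
        np.array(list(TABLE1_ROWS.values())),
    )


@pytest.fixture
def serum_tsv(tmp_path, serum_matrix):
    path = tmp_path / "serum.tsv"
    lines = ["gene_id\t" + "\t".join(TABLE1_FEATURES)]
    for gid, row in TABLE1_ROWS.items():
        lines.append(gid + "\t" + "\t".join(repr(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def fixture_1d():
    """The hand-worked 1-D instance: points {0,2,10,12}, centroids {1,11}."""
    points = np.array([[0.0], [2.0], [10.0], [12.0]])
    centroids = np.array([[1.0], [11.0]])
    return points, centroids
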