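import numpy as np
import pytest

from mivmsim.grid import RectilinearGrid, graded_axis


def test_graded_axis_hits_breakpoints_and_spacing():
    faces = graded_axis([(0.0, 1e-3, 2.5e-4), (1e-3, 4e-3, 1e-3)])
    assert faces[0] == 0.0 and faces[-1] == pytest.approx(4e-3)
    assert 1e-3 in faces  # material interfaces must land on faces
    assert np.all(np.diff(faces) > 0)


def test_graded_axis_rejects_gaps_and_bad_spacing():
    with pytest.raises(ValueError):
        graded_axis([(0.0, 1.0, 0.1), (2.0, 3.0, 0.1)])
    with pytest.raises(ValueError):
        graded_axis([(0.0, 1.0, -0.1)])


def test_cell_volumes_and_centres():
    g = RectilinearGrid([0, 1, 3], [0, 2], [0, 1, 2, 4])
    vols = g.cell_volumes()
    assert vols.shape == (2, 1, 3)
    assert vols.sum() == pytest.approx(3 * 2 * 4)
    assert g.xc[1] == pytest.approx(2.0)


def test_vtk_export_is_readable_text(tmp_path):
    g = RectilinearGrid([0, 1, 2], [0, 1], [0, 1])
    data = np.arange(2.0).reshape(2, 1, 1)
    path = tmp_path / "grid.vtk"
    g.write_vtk(path, {"field": data})
    text = path.read_text()
    assert "DATASET RECTILINEAR_GRID" in text
    assert "DIMENSIONS 3 2 2" in text
    assert "SCALARS field double 1" in text
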