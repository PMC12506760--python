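import numpy as np
import pytest

from wingmorph.io_contours import Contour


@pytest.fixture
def circle_contour():
    def make(radius=1.0, V=256, center=(0.0, 0.0), specimen="circ",
             element="wing_contour"):
        t = np.linspace(0.0, 2.0 * np.pi, V, endpoint=False)
        pts = np.c_[center[0] + radius * np.cos(t),
                    center[1] + radius * np.sin(t)]
        return Contour.create(specimen, element, pts)
    return make


@pytest.fixture
def ellipse_contour():
    def make(a=2.0, b=1.0, V=512, angle=0.0, center=(0.0, 0.0),
             specimen="ell", element="wing_contour"):
        t = np.linspace(0.0, 2.0 * np.pi, V, endpoint=False)
        pts = np.c_[a * np.cos(t), b * np.sin(t)]
        if angle:
            R = np.array([[np.cos(angle), -np.sin(angle)],
                          [np.sin(angle), np.cos(angle)]])
            pts = pts @ R.T
        pts += center
        return Contour.create(specimen, element, pts)
    return make


@pytest.fixture
def square_points():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
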