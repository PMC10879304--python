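import numpy as np
import pytest

from ppvkit.beats import BeatSeries
from ppvkit.filters import AnalysisWindow, VentilatorSetting, window_qc


@pytest.fixture
def regular_series():
    """60 beats at exactly 1-s intervals, constant PP 50 mmHg."""
    t = np.arange(60, dtype=float)
    return BeatSeries(t=t, pp=np.full(60, 50.0))


def make_window(t, pp, rr=10.0, vt=8.0, window_id="w00", t_start=None, duration=None):
    """Wrap raw beat arrays in a QC'd analysis window."""
    t = np.asarray(t, float)
    t0 = float(t[0]) if t_start is None else t_start
    dur = (float(t[-1]) - t0 + 1.0) if duration is None else duration
    w = AnalysisWindow(
        window_id=window_id,
        t_start=t0,
        t_end=t0 + dur,
        setting=VentilatorSetting(vt=vt, rr=rr),
        beats=BeatSeries(t=t, pp=np.asarray(pp, float)),
        phase_ref=t0,
    )
    return window_qc(w)
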