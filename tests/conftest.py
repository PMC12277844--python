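import numpy as np
import pytest

from grafteval import PSTH, BaselineStats, StimulusProtocol

N_BINS_DEFAULT = 750  # 15 s at 20 ms


@pytest.fixture
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture
def make_psth():
    """Factory for PSTHs with explicit bin rates (15-s trial, 20-ms bins)."""

    def _make(rates, bin_width=0.020, n_trials=1, smoothed=False) -> PSTH:
        rates = np.asarray(rates, float)
        edges = np.arange(len(rates) + 1) * bin_width
        return PSTH(bin_edges=edges, rates=rates, bin_width=bin_width,
                    n_trials=n_trials, smoothed=smoothed)

    return _make


@pytest.fixture
def make_flash_rates():
    """Noiseless rate vectors with plateau responses in the flash windows.

    Plateaus are 8 bins wide so the order-4 binomial filter leaves their
    interior bins untouched; the onset plateau sits inside (2, 2.5] s and the
    offset plateau inside [4.05, 4.3] s of the default protocol.
    """

    def _make(baseline, onset_amp=0.0, offset_amp=0.0, dark_wiggle=0.0):
        rates = np.full(N_BINS_DEFAULT, float(baseline))
        if dark_wiggle:
            # alternate dark bins around the baseline to give a nonzero SD
            dark = slice(250, 750)
            idx = np.arange(250, 750)
            rates[idx] = baseline + dark_wiggle * np.where(idx % 2 == 0, 1.0, -1.0)
        if onset_amp:
            rates[103:111] = baseline + onset_amp
        if offset_amp:
            rates[205:213] = baseline + offset_amp
        return rates

    return _make


@pytest.fixture
def baseline_of():
    def _make(mean, sd=0.0, k=4.0) -> BaselineStats:
        return BaselineStats(mean_rate=mean, sd_rate=sd, threshold=mean + k * sd)

    return _make
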