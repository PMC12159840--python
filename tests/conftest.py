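import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from pritdose.pk import OnePhaseDecayFit


@pytest.fixture
def gemini_tumor_fit() -> OnePhaseDecayFit:
    """Bivalent-radiohapten tumor kinetics: published plateau 4.5 %ID/g and
    biological half-life 25.4 h, A0 anchored so the curve passes through the
    published 2 h mean of 14.0 %ID/g."""
    return OnePhaseDecayFit(A0=14.53, plateau=4.5, t_half_bio_h=25.4)


@pytest.fixture
def biodist_csv(tmp_path: Path) -> Path:
    path = tmp_path / "biodist.csv"
    path.write_text(
        "animal_id,group,tissue,time_h,pct_id_g\n"
        "m1,Gemini-48h,tumor,2,13.5\n"
        "m2,Gemini-48h,tumor,2,14.5\n"
        "m3,Gemini-48h,blood,2,3.1\n"
    )
    return path
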