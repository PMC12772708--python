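"""Bundled example data.

``load_example_cohort`` returns a small longitudinal hemodynamics table for
four pediatric pulmonary arterial hypertension patients studied at baseline
and at a follow-up roughly two years later: model-derived MPA stiffness
(reported in the source's printed pressure-unit convention) and pulmonary
arterial compliance, plus catheter-derived mean and pulse pulmonary artery
pressures and the pulmonary vascular resistance index.  It is the worked
example for the longitudinal-comparison utilities.
"""
from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["load_example_cohort"]

_COHORT_CSV = """\
patient,metric,units,baseline,followup
1,mPAP,mmHg,59.4,113.3
1,pulse_pressure,mmHg,30.6,61.7
1,MPA_stiffness,MPa,134683.6,430298.3
1,pulmonary_compliance,mm4*s2/g,8.45,6.54
1,PVRi,WU*m2,16.2,18.2
2,mPAP,mmHg,82.9,55.0
2,pulse_pressure,mmHg,66.2,61.8
2,MPA_stiffness,MPa,324985.9,350659.5
2,pulmonary_compliance,mm4*s2/g,3.45,4.33
3,MPA_stiffness,MPa,100562.5,71609.6
3,pulmonary_compliance,mm4*s2/g,20.49,16.45
3,PVRi,WU*m2,7.3,9.1
4,mPAP,mmHg,50.1,27.3
4,pulse_pressure,mmHg,33.3,27.7
4,MPA_stiffness,MPa,190034.9,98286.2
4,pulmonary_compliance,mm4*s2/g,7.03,10.60
"""


def load_example_cohort() -> pd.DataFrame:
    """Four-patient, two-timepoint example hemodynamics table."""
    return pd.read_csv(StringIO(_COHORT_CSV))
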