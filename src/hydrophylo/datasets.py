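"""Packaged species-mean dataset.

Climate and trait means for the 14 Tasmanian eucalypt species: site maximum
temperature in the warmest month (``maxT``, deg C), minimum temperature in
the coldest month (``minT``, deg C) and precipitation in the driest quarter
(``Pdq``, mm), together with species means of P50 (MPa), g_min
(mmol m^-2 s^-1, at 25 deg C) and T_P (deg C).  Standard errors accompany
P50 and g_min; T_P has none because it is read from one mean curve per
species.  Eight species belong to subgenus Symphyomyrtus and six to
subgenus Eucalyptus.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["load_species_table"]

_TABLE = """\
species,abbrev,subgenus,maxT,minT,Pdq,p50,p50_se,gmin,gmin_se,tp
E. archeri,arch,Symphyomyrtus,15.8,-2.2,237,-5.67,0.08,7.60,0.71,35.83
E. barberi,barb,Symphyomyrtus,21.2,3.3,158,-4.08,0.36,5.70,0.70,34.17
E. dalrympleana,dalr,Symphyomyrtus,19.6,1.1,150,-5.03,0.36,6.64,1.12,40.86
E. globulus,glob,Symphyomyrtus,22.2,3.1,123,-5.06,0.22,7.00,0.97,37.38
E. gunnii,gunn,Symphyomyrtus,17.1,-1.6,212,-6.43,0.57,3.97,0.48,32.84
E. johnstonii,john,Symphyomyrtus,18.7,1.6,224,-4.76,0.41,8.80,0.92,34.60
E. vernicosa,vern,Symphyomyrtus,17.4,0,256,-5.45,0.41,10.01,1.26,29.78
E. viminalis,vimi,Symphyomyrtus,22,3.5,126,-4.69,0.26,4.88,1.07,35.24
E. amygdalina,amyg,Eucalyptus,21.4,3.9,148,-4.60,0.30,4.20,0.42,35.69
E. coccifera,cocc,Eucalyptus,14.5,-1,215,-4.80,0.23,6.86,0.82,31.70
E. nitida,niti,Eucalyptus,18,0.2,248,-3.68,0.21,5.43,0.40,31.59
E. pulchella,pulc,Eucalyptus,21.7,3.7,135,-5.17,0.16,4.29,0.37,35.74
E. regnans,regn,Eucalyptus,19.7,2.2,205,-4.11,0.30,5.58,0.33,35.89
E. risdonii,risd,Eucalyptus,22,3.5,126,-5.58,0.21,3.04,1.02,36.46
"""


def load_species_table() -> pd.DataFrame:
    """Species-mean climate and trait table, indexed by species name."""
    df = pd.read_csv(StringIO(_TABLE))
    return df.set_index("species")
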