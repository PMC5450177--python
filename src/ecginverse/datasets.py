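"""Bundled reference tables.

Two small published benchmark tables are shipped inline so the package's
arithmetic can be checked without network access:

* a per-record R/T detection performance table for the first channel of
  16 MIT-BIH arrhythmia records (beat totals, FN/FP counts and the
  derived DER/Se/Accuracy percentages), and
* fitted ``(k, h_R, h_L)`` triples with clinical labels for 41
  pathological/normal ECG samples (European ST-T ischemia records,
  BIDMC congestive-heart-failure records, and normal ECG-ID records).
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_detector_benchmark", "load_pathology_fits"]

_DETECTOR_BENCHMARK_CSV = """\
record,total,fn_r,fn_t,fp_r,fp_t,der_r,der_t,se_r,se_t,acc_r,acc_t
200,2601,1,1,6,8,0.27,0.35,99.96,99.96,99.73,99.65
201,1963,0,1,2,2,0.10,0.15,100.00,99.95,99.90,99.85
202,2136,1,2,7,9,0.38,0.52,99.95,99.91,99.63,99.49
203,2980,11,12,5,6,0.54,0.61,99.63,99.60,99.46,99.40
205,2656,1,1,0,1,0.04,0.08,99.96,99.96,99.96,99.92
207,1862,0,1,1,1,0.05,0.11,100.00,99.95,99.95,99.89
208,2955,8,9,5,5,0.44,0.48,99.73,99.69,99.56,99.53
209,3005,1,1,0,1,0.03,0.07,99.97,99.97,99.97,99.93
210,2650,6,7,3,4,0.34,0.42,99.77,99.74,99.66,99.58
215,3363,0,1,0,0,0.00,0.03,100.00,99.97,100.00,99.97
217,2208,2,2,2,3,0.18,0.23,99.91,99.91,99.82,99.77
219,2154,1,0,2,2,0.14,0.09,99.95,100.00,99.86,99.91
220,2048,1,1,1,1,0.10,0.10,99.95,99.95,99.90,99.90
223,2605,2,1,0,0,0.08,0.04,99.92,99.96,99.92,99.96
228,2053,7,7,7,8,0.69,0.74,99.66,99.66,99.32,99.27
230,2256,1,1,3,3,0.18,0.18,99.96,99.96,99.82,99.82
"""

_PATHOLOGY_FITS_CSV = """\
record,k,h_r,h_l,clinical_label
E0111,0.71,0.97,0.95,myocardial_ischemia
E0112,0.79,0.89,0.87,myocardial_ischemia
E0113,0.69,0.91,0.93,myocardial_ischemia
E0114,0.63,0.93,0.92,myocardial_ischemia
E0115,0.96,0.99,0.91,myocardial_ischemia
E0116,0.71,0.88,0.92,myocardial_ischemia
E0117,0.73,0.89,0.88,myocardial_ischemia
E0118,0.71,0.91,0.87,myocardial_ischemia
E0112,0.69,0.91,0.93,myocardial_ischemia
E0113,0.63,0.93,0.92,myocardial_ischemia
E0114,0.66,0.89,0.91,myocardial_ischemia
E0115,0.71,0.88,0.92,myocardial_ischemia
E0116,0.70,0.86,0.88,myocardial_ischemia
E0117,0.79,0.87,0.87,myocardial_ischemia
E0118,0.63,0.91,0.93,myocardial_ischemia
Chf01,1.79,0.81,0.83,heart_failure
Chf02,1.62,0.79,0.81,heart_failure
Chf03,1.16,0.91,0.97,heart_failure
Chf04,1.70,0.86,0.88,heart_failure
Chf05,1.69,0.79,0.86,heart_failure
Chf06,1.79,0.87,0.83,heart_failure
Chf07,1.62,0.79,0.81,heart_failure
Chf08,1.66,0.81,0.77,heart_failure
Chf09,1.10,0.92,0.98,heart_failure
Chf10,1.69,0.99,0.86,heart_failure
Chf11,1.79,0.89,0.83,heart_failure
Chf12,1.62,0.89,0.81,heart_failure
Chf13,1.65,0.81,0.77,heart_failure
Chf14,1.71,0.82,0.88,heart_failure
Chf15,1.68,0.79,0.86,heart_failure
Person_01/rec_1,1.01,0.98,0.99,normal
Person_01/rec_1,1.02,1.04,1.01,normal
Person_01/rec_1,0.99,1.02,0.97,normal
Person_01/rec_1,1.01,0.97,0.99,normal
Person_01/rec_1,1.05,0.99,1.02,normal
Person_01/rec_1,1.01,0.98,0.99,normal
Person_01/rec_1,1.04,0.98,0.99,normal
Person_01/rec_1,1.02,1.01,1.01,normal
Person_01/rec_1,0.99,1.02,0.97,normal
Person_01/rec_1,1.01,0.97,0.99,normal
Person_01/rec_1,1.00,0.98,1.02,normal
"""


def load_detector_benchmark() -> pd.DataFrame:
    """Per-record detection counts and percentages (16 MIT-BIH records)."""
    return pd.read_csv(io.StringIO(_DETECTOR_BENCHMARK_CSV))


def load_pathology_fits() -> pd.DataFrame:
    """Fitted (k, h_R, h_L) triples with clinical labels (41 samples)."""
    return pd.read_csv(io.StringIO(_PATHOLOGY_FITS_CSV))
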