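"""Bundled cross-classification tables from a published IAS study.

Each table cross-tabulates two ways of classifying the same prostate-cancer
patients into response categories: clinical outcome groups assigned by
physicians (without relapse / metastasis / androgen independence) or model
-based Types (i)/(ii)/(iii) obtained by fitting PSA records of varying
length.  They are the standard worked examples for the exact r x c Fisher
test in this package; rows/columns follow the published layout.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ContingencyTable

_MD = ("without_relapse", "metastasis", "androgen_independence")
_TY = ("type_i", "type_ii", "type_iii")


def _t(counts, rows=_MD, cols=_TY) -> ContingencyTable:
    return ContingencyTable(counts=np.array(counts, dtype=np.int64),
                            row_labels=rows, col_labels=cols)


#: physician outcome vs earlier prior-free fitting method, whole records
MD_VS_ORIGINAL_FULL = _t([[35, 42, 4], [7, 13, 1], [9, 22, 6]])

#: physician outcome vs MAP fits of whole records
MD_VS_MAP_FULL = _t([[61, 14, 6], [9, 9, 3], [12, 18, 7]])

#: MAP fits of whole records vs the earlier prior-free method
MAP_FULL_VS_ORIGINAL = _t([[40, 40, 3], [9, 30, 3], [4, 7, 5]], rows=_TY)

#: MAP whole-record fits vs MAP fits of the first one and a half cycles
MAP_FULL_VS_MAP_ONEHALF = _t([[66, 17, 0], [11, 28, 3], [2, 2, 12]],
                             rows=_TY)

#: physician outcome vs MAP fits of the first one and a half cycles
MD_VS_MAP_ONEHALF = _t([[56, 18, 7], [7, 11, 3], [15, 17, 5]])

#: MAP one-and-a-half-cycle fits vs the earlier prior-free method
MAP_ONEHALF_VS_ORIGINAL = _t([[37, 38, 4], [11, 32, 4], [5, 7, 3]],
                             rows=_TY)

#: MAP whole-record fits vs MAP fits of the first half cycle only
MAP_FULL_VS_MAP_HALF = _t([[59, 22, 2], [23, 18, 1], [13, 2, 1]], rows=_TY)

#: physician outcome vs MAP fits of the first half cycle only
MD_VS_MAP_HALF = _t([[56, 23, 2], [15, 5, 1], [23, 13, 1]])

#: generating classifications vs refits of artificial pre-treatment series
GENERATOR_VS_REFIT_PREOFF = _t([[13, 6, 0], [6, 6, 2], [3, 0, 0]], rows=_TY)

#: all bundled tables, keyed by a short slug
CLASSIFICATION_TABLES = {
    "md_vs_original_full": MD_VS_ORIGINAL_FULL,
    "md_vs_map_full": MD_VS_MAP_FULL,
    "map_full_vs_original": MAP_FULL_VS_ORIGINAL,
    "map_full_vs_map_onehalf": MAP_FULL_VS_MAP_ONEHALF,
    "md_vs_map_onehalf": MD_VS_MAP_ONEHALF,
    "map_onehalf_vs_original": MAP_ONEHALF_VS_ORIGINAL,
    "map_full_vs_map_half": MAP_FULL_VS_MAP_HALF,
    "md_vs_map_half": MD_VS_MAP_HALF,
    "generator_vs_refit_preoff": GENERATOR_VS_REFIT_PREOFF,
}
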