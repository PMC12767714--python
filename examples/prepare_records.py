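"""Harmonize raw service fields into the 12 binary indicators, summarize
them with survey weights, and fill missing cells by chained equations.

Note the antenatal-care rule: 4+ visits qualifies for surveys before 2017,
8+ from 2017 on, so the same woman-record can flip depending on survey year.
"""

import numpy as np
import pandas as pd

from careclass import (PreparedDataset, harmonize_indicators, chained_impute,
                       weighted_summaries, published_profile_config, simulate,
                       inject_missing, INDICATOR_NAMES)

raw = pd.DataFrame({
    "country_id": ["Kenya", "Kenya", "Mali", "Mali"],
    "survey_year": [2016, 2016, 2022, 2022],
    "weight": [1.1, 0.9, 1.3, 0.7],
    "anc_visits": [4, 2, 4, 8],
    "tetanus_doses": [2, 1, 0, 3],
    "dpt_doses": [3, 2, 3, 3],
    "polio_doses": [3, 3, 1, 3],
    "facility_delivery": [1, 0, 1, 1],
    "skilled_attendant": [1, 0, 1, 1],
    "pnc_mother_2d": [1, 0, 0, 1],
    "pnc_newborn_2d": [1, 0, 0, 1],
    "modern_fp": [0, 0, 1, 1],
    "bcg": [1, 1, 1, 1],
    "measles": [1, 0, 1, 1],
    "age_appropriate_bf": [1, 1, 0, 1],
})
mat, errors = harmonize_indicators(raw)
anc = mat.values[:, INDICATOR_NAMES.index("anc4")]
print(f"ANC indicator: {anc.tolist()} — 4 visits qualifies in 2016 but not in 2022")

ind, country = weighted_summaries(PreparedDataset(indicators=mat))
print("\nweighted service coverage (% of weighted sample):")
print(ind.to_string(index=False))
print("\ncountry shares:")
print(country.to_string(index=False))

# chained-equation imputation on a larger simulated table with 10% MCAR holes
config = published_profile_config(J=10, n_per_group=300, seed=11)
data, _, _ = simulate(config)
holey = inject_missing(data, rate=0.10, mechanism="MCAR", seed=2)
completed = chained_impute(PreparedDataset(indicators=holey), cycles=5, m=3, seed=3)
shift = np.abs(np.mean([d.indicators.values.mean(0) for d in completed], axis=0)
               - data.values.mean(0)).max()
print(f"\nimputed {np.isnan(holey.values).sum()} of {holey.values.size} cells "
      f"across m=3 datasets; max marginal-mean shift vs pre-masking truth {shift:.3f}")
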