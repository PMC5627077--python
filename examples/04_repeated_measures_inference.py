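"""Full study emulation: 6 familiar + 6 unfamiliar groups, two sampling
periods, repeated-measures mixed models and BH FDR.

Familiar groups get extra alignment strength in the generator, so the
familiarity term of the polarization model should come out positive.
"""

from shoalkit import (
    SimConfig,
    StudyDesignConfig,
    benjamini_hochberg,
    fit_group_model,
    fit_individual_model,
    fits_table,
)
from shoalkit.pipeline import study_metric_tables

design = StudyDesignConfig(seed=4)  # familiarity_alignment_delta = 1.0
gdf, idf = study_metric_tables(design, SimConfig(duration=60.0))

fits = (
    fit_group_model(gdf)
    + fit_individual_model(idf, "log_speed")
    + fit_individual_model(idf, "log_nnd")
)
table = fits_table(fits)
tests = table[table["term"] != "intercept"].reset_index(drop=True)
fdr = benjamini_hochberg(tests["p_value"], q=0.05)
tests = tests.assign(significant=fdr.significant)

cols = ["response", "term", "estimate", "std_error", "t_value", "df", "p_value", "significant"]
print(tests[cols].round(4).to_string(index=False))
print()
print("A positive, significant familiarity term for mean_polarization recovers the")
print("injected effect: familiar shoals are more aligned.  df=10 reflects the 12")
print("groups (between-subjects); df=46 the 96 fish-period observations (within).")
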