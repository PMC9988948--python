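"""The worked 3-species cohort whose every number is hand-checkable.

'alpha' is a deliberately poor species (fragmented, gappy assembly and a
protein-coding-only annotation), 'gamma' a polished one, 'beta' sits in
between.  Every indicator, MQI, QQI and index value can be re-derived with
pencil and paper from the fixture's counts.
"""

import tempfile
from pathlib import Path

from refqual import score_cohort, worked_micro_cohort

with tempfile.TemporaryDirectory() as tmp:
    cohort = worked_micro_cohort(Path(tmp))
    result = score_cohort(cohort.manifest_path)
    table = result.matrix.to_table().drop(columns=["busco_completeness"])
    print(table.round(6).to_string())
    print()
    div = result.matrix.diversity
    print(f"PC1 variance explained: {div.variance_explained_pc1:.4f}")
    print("(the three biotype profiles lie on one compositional line,")
    print(" so a single principal axis carries all the variance)")
    print(f"\nRanking: {' > '.join(result.ranked.index)}")
    print("alpha scores 0.45: last in every cohort-relative column and")
    print("weakest in every empirical rate; gamma scores 0.952.")
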