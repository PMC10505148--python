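"""Compute the variability-measure battery from forced-aligner TextGrids.

Reads the two bundled fixture TextGrids (a truncated diadochokinetic AMR
sample and a short read-speech sample), applies the token-selection rules
and prints the measure table.
"""

from pathlib import Path

import speechvar as sv
from speechvar.measures import compute_measure_table

DATA = Path(__file__).resolve().parent.parent / "tests" / "data"

amr = sv.read_textgrid(
    DATA / "P01_AMR.TextGrid", {"phone": "phones", "trial": "trials"}, "P01", "AMR"
)
read = sv.read_textgrid(DATA / "P02_READ.TextGrid", {"phone": "phones"}, "P02", "READ")

print(f"AMR sample: {len(amr)} segments, {len(amr.trial_windows)} trial windows "
      f"(complete battery needs 12: complete={amr.complete})")

tokens = sv.select_stop_tokens(amr, "voiceless")
print(f"voiceless stop tokens: n={tokens.n}, VOTs (s): {tokens.values[:5].round(3)} ...")

table = compute_measure_table([amr, read])
print("\nMeasure table (raw = measure units; log = natural log used in analyses):")
print(table.data.to_string(index=False))

# Reading: vot_cov_voiceless is SD/mean of the voice-onset-times (unitless);
# speech_rate_mean is syllables/second; rows with a missing_reason had too
# few tokens for a stable estimate (fewer than 5 by default).
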