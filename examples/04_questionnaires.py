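"""Score ESS and EQ5 questionnaire responses.

The 15 ESS statements are rated 0 (strongly disagree) to 4 (strongly
agree) and summed to 0-60.  The five EQ5 dimensions are rated 1 (worst)
to 5 (best); the 0-100 health-state assessment is mapped onto the same
1-5 scale and added, giving a 6-30 cumulative score.
"""

import datetime as dt

from wearwell import Eq5Response, EssResponse, map_hsa, score_eq5, score_ess

ts = dt.datetime(2019, 5, 14, 18, 30)

ess = EssResponse("demo", ts, items=(4, 3, 3, 2, 4, 3, 2, 3, 4, 2, 3, 3, 2, 4, 3))
print(f"ESS items {ess.items}")
print(f"  cumulative ESS score = {score_ess(ess)} (range 0-60, higher is better)")

eq5 = Eq5Response("demo", ts, dimensions=(4, 5, 4, 3, 4), hsa=72.0)
print(f"EQ5 dimensions {eq5.dimensions}, health-state assessment {eq5.hsa:.0f}/100")
print(f"  mapped hsa = 1 + 4*{eq5.hsa:.0f}/100 = {map_hsa(eq5.hsa):.2f}")
print(f"  cumulative EQ5 score = {score_eq5(eq5):.2f} (range 6-30)")
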