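"""The 2x2 worked example: every quantity checkable by hand.

Two population centers (care demands 10 and 20) face two candidate sites
with crossed distances (1 km to the near site, 2 km to the far one).
"""

import numpy as np

from rcfopt import (
    FacilityConfiguration,
    equity_objective,
    gravity_accessibility,
    micro_instance,
    profit_objective,
    size_beds_to_demand,
    travel_cost_objective,
)

m1 = micro_instance()
print(f"total care demand W = {m1.total_demand:.0f}")

# open both sites and size beds to the demand each site attracts
config = size_beds_to_demand(m1, [0, 1])
print(f"demand-sized beds    = {config.beds}  (sum = W)")

# with beds (15, 30) the gravity field is (1.35, 1.575): each center's
# supply-to-demand ratio after distance-decayed competition
with_beds = FacilityConfiguration(
    open=np.array([1, 1]), beds=np.array([15.0, 30.0]),
    allocation=config.allocation, p=2,
)
field = gravity_accessibility(m1, with_beds)
print(f"accessibility        = {field.values}  (beds per person)")
print(f"weighted mean        = {field.weighted_mean}  (= V/W = 45/30)")
print(f"equity objective     = {equity_objective(field)}  (sum of squared deviations)")

# travel cost under nearest allocation, and the investor's mean margin
print(f"travel cost          = {travel_cost_objective(m1, config.allocation):.0f} m*persons")
print(f"mean profit          = {profit_objective(m1, config)[0]:.0f} RMB/month/facility")
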