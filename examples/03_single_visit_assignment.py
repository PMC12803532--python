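"""Assign a participant to a trajectory from one echocardiogram.

Because trajectories are group-level curves, Bayes' rule gives a posterior
over groups from any subset of observations - here a single visit with
LVEF and E/A measured at age 75.
"""

import numpy as np

import cardiotraj as ct
from cardiotraj.trajectory import (AgeBasis, GroupParameters, ObservationSet,
                                   TrajectoryModel)

# a small fitted-style model: low-LVEF, normal, and supranormal groups
groups = [
    GroupParameters({"lvef": np.array([50.0, -4.0, 0.0]), "ea": np.array([0.75, 0.0, 0.0])},
                    {"lvef": 6.0, "ea": 0.15}),
    GroupParameters({"lvef": np.array([67.0, 2.0, 0.0]), "ea": np.array([1.0, -0.1, 0.0])},
                    {"lvef": 7.0, "ea": 0.2}),
    GroupParameters({"lvef": np.array([80.0, 3.0, 0.0]), "ea": np.array([0.95, -0.08, 0.0])},
                    {"lvef": 6.0, "ea": 0.25}),
]
model = TrajectoryModel(k_max=3, weights=[0.2, 0.6, 0.2], groups=groups,
                        concentration=1.0, basis=AgeBasis(), priors={})

obs = ObservationSet("participant-42", [75.0], {"lvef": [45.0], "ea": [0.8]})
post = ct.posterior_membership(model, obs)
print("posterior over groups:", np.round(post.probabilities, 3))
print(f"MAP group: {post.map_group} "
      "(group 0 = declining-LVEF; LVEF 45% at 75 y is far below the other "
      "group curves despite group 0's smaller prior weight)")

obs2 = ObservationSet("participant-43", [75.0], {"lvef": [np.nan], "ea": [0.8]})
post2 = ct.posterior_membership(model, obs2)
print("with LVEF missing, E/A alone is less informative:",
      np.round(post2.probabilities, 3))
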