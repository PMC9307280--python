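"""Literature defaults for the shipped arterial networks.

The 83-segment systemic tree (including the 22 carotid/cerebral segments
forming and feeding the circle of Willis), the Windkessel outlet loads, the
lumped body blocks and the elastance heart are "literature defaults": the
geometry and parameter values are assembled from the classic systemic-tree
and cerebral-network modelling literature, not measured for any patient.
Every value can be overridden through the network config file.
"""

# (id, name, length mm, diameter mm, group)
# group: "aorta" segments receive the age adjustment; "cerebral" segments are
# the 22 carotid/cerebral arteries whose diameter/length are model inputs.
SEGMENTS = [
    (0, "Ascending aorta", 40.0, 28.0, "aorta"),
    (1, "Aortic arch A", 20.0, 25.0, "aorta"),
    (2, "Brachiocephalic", 34.0, 12.0, "systemic"),
    (3, "Aortic arch B", 39.0, 22.0, "aorta"),
    (4, "Thoracic aorta A", 52.0, 20.0, "aorta"),
    (5, "Thoracic aorta B", 104.0, 16.0, "aorta"),
    (6, "Abdominal aorta A", 53.0, 13.0, "aorta"),
    (7, "Celiac", 20.0, 8.0, "systemic"),
    (8, "Hepatic", 66.0, 5.0, "systemic"),
    (9, "Splenic", 63.0, 4.0, "systemic"),
    (10, "Gastric", 71.0, 3.0, "systemic"),
    (11, "Abdominal aorta B", 15.0, 12.5, "aorta"),
    (12, "Superior mesenteric", 59.0, 8.0, "systemic"),
    (13, "Abdominal aorta C", 15.0, 12.0, "aorta"),
    (14, "R. renal", 32.0, 5.0, "systemic"),
    (15, "Abdominal aorta D", 15.0, 11.5, "aorta"),
    (16, "L. renal", 32.0, 5.0, "systemic"),
    (17, "R. gonadal", 200.0, 3.0, "systemic"),
    (18, "L. gonadal", 200.0, 3.0, "systemic"),
    (19, "Abdominal aorta E", 125.0, 11.0, "aorta"),
    (20, "Inferior mesenteric", 50.0, 4.0, "systemic"),
    (21, "Lumbar", 60.0, 3.0, "systemic"),
    (22, "R. com. iliac", 58.0, 8.0, "systemic"),
    (23, "L. com. iliac", 58.0, 8.0, "systemic"),
    (24, "R. ext. iliac", 144.0, 6.5, "systemic"),
    (25, "R. int. iliac", 50.0, 4.0, "systemic"),
    (26, "R. femoral", 300.0, 5.0, "systemic"),
    (27, "R. deep femoral", 126.0, 4.0, "systemic"),
    (28, "R. ant. tibial", 343.0, 3.0, "systemic"),
    (29, "R. post. tibial", 321.0, 3.5, "systemic"),
    (30, "R. peroneal", 320.0, 3.0, "systemic"),
    (31, "L. ext. iliac", 144.0, 6.5, "systemic"),
    (32, "L. int. iliac", 50.0, 4.0, "systemic"),
    (33, "L. femoral", 300.0, 5.0, "systemic"),
    (34, "L. deep femoral", 126.0, 4.0, "systemic"),
    (35, "L. ant. tibial", 343.0, 3.0, "systemic"),
    (36, "L. post. tibial", 321.0, 3.5, "systemic"),
    (37, "L. peroneal", 320.0, 3.0, "systemic"),
    (38, "R. coronary", 100.0, 3.5, "systemic"),
    (39, "L. coronary", 100.0, 4.0, "systemic"),
    (40, "Intercostals", 80.0, 6.0, "systemic"),
    (41, "R. subclavian A", 34.0, 9.0, "systemic"),
    (42, "R. subclavian B", 68.0, 8.0, "systemic"),
    (43, "R. int. thoracic", 150.0, 3.0, "systemic"),
    (44, "R. axillary", 80.0, 7.0, "systemic"),
    (45, "R. brachial", 220.0, 6.0, "systemic"),
    (46, "R. radial", 230.0, 3.0, "systemic"),
    (47, "R. ulnar A", 67.0, 4.0, "systemic"),
    (48, "R. ulnar B", 170.0, 3.5, "systemic"),
    (49, "R. interosseous", 79.0, 2.0, "systemic"),
    (50, "L. subclavian A", 34.0, 9.0, "systemic"),
    (51, "L. subclavian B", 68.0, 8.0, "systemic"),
    (52, "L. int. thoracic", 150.0, 3.0, "systemic"),
    (53, "L. axillary", 80.0, 7.0, "systemic"),
    (54, "L. brachial", 220.0, 6.0, "systemic"),
    (55, "L. radial", 230.0, 3.0, "systemic"),
    (56, "L. ulnar A", 67.0, 4.0, "systemic"),
    (57, "L. ulnar B", 170.0, 3.5, "systemic"),
    (58, "L. interosseous", 79.0, 2.0, "systemic"),
    (59, "R. ext. carotid", 110.0, 4.5, "systemic"),
    (60, "L. ext. carotid", 110.0, 4.5, "systemic"),
    (61, "R. com. carotid", 170.0, 7.0, "cerebral"),
    (62, "L. com. carotid", 180.0, 7.0, "cerebral"),
    (63, "R. int. carotid I", 160.0, 4.2, "cerebral"),
    (64, "L. int. carotid I", 160.0, 4.2, "cerebral"),
    (65, "R. int. carotid II", 7.0, 4.0, "cerebral"),
    (66, "L. int. carotid II", 7.0, 4.0, "cerebral"),
    (67, "R. vertebral", 190.0, 3.0, "cerebral"),
    (68, "L. vertebral", 190.0, 3.0, "cerebral"),
    (69, "Basilar", 25.0, 3.2, "cerebral"),
    (70, "R. ant. cerebral I", 15.0, 2.3, "cerebral"),
    (71, "L. ant. cerebral I", 15.0, 2.3, "cerebral"),
    (72, "R. ant. cerebral II", 25.0, 2.2, "cerebral"),
    (73, "L. ant. cerebral II", 25.0, 2.2, "cerebral"),
    (74, "R. mid. cerebral", 30.0, 2.9, "cerebral"),
    (75, "L. mid. cerebral", 30.0, 2.9, "cerebral"),
    (76, "R. post. cerebral I", 10.0, 2.2, "cerebral"),
    (77, "L. post. cerebral I", 10.0, 2.2, "cerebral"),
    (78, "R. post. cerebral II", 25.0, 2.1, "cerebral"),
    (79, "L. post. cerebral II", 25.0, 2.1, "cerebral"),
    (80, "Ant. comm.", 4.0, 1.5, "cerebral"),
    (81, "R. post. comm.", 15.0, 1.4, "cerebral"),
    (82, "L. post. comm.", 15.0, 1.4, "cerebral"),
]

# Junctions: lists of (segment id, end) with end "d" (distal) or "p"
# (proximal).  Mass and total pressure are enforced across every listed end,
# which also covers the merging and ring topology of the circle of Willis.
JUNCTIONS = [
    [(0, "d"), (1, "p"), (38, "p"), (39, "p")],
    [(1, "d"), (2, "p"), (3, "p"), (62, "p")],
    [(2, "d"), (41, "p"), (61, "p")],
    [(3, "d"), (4, "p"), (50, "p")],
    [(4, "d"), (5, "p"), (40, "p")],
    [(5, "d"), (6, "p")],
    [(6, "d"), (7, "p"), (11, "p")],
    [(7, "d"), (8, "p"), (9, "p"), (10, "p")],
    [(11, "d"), (12, "p"), (13, "p")],
    [(13, "d"), (14, "p"), (15, "p")],
    [(15, "d"), (16, "p"), (17, "p"), (18, "p"), (19, "p")],
    [(19, "d"), (20, "p"), (21, "p"), (22, "p"), (23, "p")],
    [(22, "d"), (24, "p"), (25, "p")],
    [(24, "d"), (26, "p"), (27, "p")],
    [(26, "d"), (28, "p"), (29, "p"), (30, "p")],
    [(23, "d"), (31, "p"), (32, "p")],
    [(31, "d"), (33, "p"), (34, "p")],
    [(33, "d"), (35, "p"), (36, "p"), (37, "p")],
    [(41, "d"), (42, "p"), (67, "p"), (43, "p")],
    [(42, "d"), (44, "p")],
    [(44, "d"), (45, "p")],
    [(45, "d"), (46, "p"), (47, "p")],
    [(47, "d"), (48, "p"), (49, "p")],
    [(50, "d"), (51, "p"), (68, "p"), (52, "p")],
    [(51, "d"), (53, "p")],
    [(53, "d"), (54, "p")],
    [(54, "d"), (55, "p"), (56, "p")],
    [(56, "d"), (57, "p"), (58, "p")],
    [(61, "d"), (63, "p"), (59, "p")],
    [(62, "d"), (64, "p"), (60, "p")],
    [(63, "d"), (65, "p")],
    [(64, "d"), (66, "p")],
    [(65, "d"), (74, "p"), (70, "p"), (81, "p")],
    [(66, "d"), (75, "p"), (71, "p"), (82, "p")],
    [(70, "d"), (72, "p"), (80, "p")],
    [(71, "d"), (73, "p"), (80, "d")],
    [(67, "d"), (68, "d"), (69, "p")],
    [(69, "d"), (76, "p"), (77, "p")],
    [(76, "d"), (78, "p"), (81, "d")],
    [(77, "d"), (79, "p"), (82, "d")],
]

INLET_SEGMENT = 0

# Fraction of cardiac output drained by each terminal segment (normalised at
# build time) and the body block ("upper"/"lower") its Windkessel feeds.
OUTLET_FRACTIONS = {
    8: (0.07, "lower"), 9: (0.05, "lower"), 10: (0.03, "lower"),
    12: (0.10, "lower"), 14: (0.09, "lower"), 16: (0.09, "lower"),
    17: (0.005, "lower"), 18: (0.005, "lower"), 20: (0.03, "lower"),
    21: (0.02, "lower"), 25: (0.035, "lower"), 27: (0.025, "lower"),
    28: (0.015, "lower"), 29: (0.020, "lower"), 30: (0.010, "lower"),
    32: (0.035, "lower"), 34: (0.025, "lower"), 35: (0.015, "lower"),
    36: (0.020, "lower"), 37: (0.010, "lower"),
    38: (0.020, "upper"), 39: (0.025, "upper"), 40: (0.040, "upper"),
    43: (0.005, "upper"), 46: (0.015, "upper"), 48: (0.015, "upper"),
    49: (0.005, "upper"), 52: (0.005, "upper"), 55: (0.015, "upper"),
    57: (0.015, "upper"), 58: (0.005, "upper"),
    59: (0.020, "upper"), 60: (0.020, "upper"),
    # circle of Willis outlets
    72: (0.016, "upper"), 73: (0.016, "upper"),
    74: (0.030, "upper"), 75: (0.030, "upper"),
    78: (0.012, "upper"), 79: (0.012, "upper"),
}

COW_OUTLETS = [72, 73, 74, 75, 78, 79]
COW_INLETS = [63, 64, 69]          # L/R internal carotid I, basilar
CEREBRAL_IDS = list(range(61, 83))
STENOSIS_HOSTS = {"right": 63, "left": 64}
MAP_SEGMENT = 50                   # left subclavian A: MAP reporting site

# Reference operating point used to size the Windkessel loads.
MAP_REF = 90.0       # mmHg
P_VENOUS_REF = 5.0   # mmHg
CO_REF = 85.0        # mL/s, full systemic network
WK_TIME_CONSTANT = 1.2   # s, sets per-outlet compliance C = tau / PR
PR_PROXIMAL_FRACTION = 0.1

# Elastic-modulus law Eh(r0) = r0 * (k1 * exp(k2 * r0) + k3), r0 in m,
# Eh in Pa.m (exponential-plus-constant empirical fit).
EH_LAW = (2.0e6, -2253.0, 8.65e4)

# Aortic age adjustment: piecewise-linear factors applied to the reference
# (age 40) aortic stiffness and diameter.
AGE_TABLE = {
    "ages": [25.0, 40.0, 60.0, 75.0, 90.0],
    "eh_factor": [0.85, 1.0, 1.35, 1.7, 2.0],
    "diameter_factor": [0.96, 1.0, 1.06, 1.12, 1.18],
}
REFERENCE_AGE = 40.0

# Body blocks (R mmHg.s/mL, L mmHg.s^2/mL, C mL/mmHg)
BODY_BLOCKS = {
    "upper": {"R": 0.12, "L": 5.0e-4, "C": 15.0},
    "lower": {"R": 0.10, "L": 5.0e-4, "C": 20.0},
}

# Time-varying elastance heart (left atrium + left ventricle, diode valves).
HEART = {
    "E_max_lv": 2.2,     # mmHg/mL
    "E_min_lv": 0.07,
    "V0_lv": 5.0,        # mL
    "E_max_la": 0.25,
    "E_min_la": 0.15,
    "V0_la": 3.0,
    "Ts_lv": 0.35,       # s, ventricular activation duration
    "t_la": 0.85,        # s, atrial activation onset within the cycle
    "Ts_la": 0.15,
    "R_mv": 0.004,       # mmHg.s/mL mitral valve
    "R_av": 0.004,       # aortic valve
    "cardiac_period": 1.0,
}

STENOSIS_LS_DEFAULT = 20.0   # mm, used for the (small) pulsatility term

# ------------------------------------------------------------------
# Five-segment toy network: one trunk feeding a "cerebral" branch with a
# stenosis host and a "systemic" branch; used for desk-scale experiments.
# ------------------------------------------------------------------
TOY_SEGMENTS = [
    (0, "Trunk", 60.0, 12.0, "aorta"),
    (1, "L. branch", 80.0, 5.0, "cerebral"),
    (2, "R. branch", 80.0, 5.0, "cerebral"),
    (3, "L. outlet artery", 40.0, 3.5, "cerebral"),
    (4, "R. outlet artery", 40.0, 3.5, "cerebral"),
]
TOY_JUNCTIONS = [
    [(0, "d"), (1, "p"), (2, "p")],
    [(1, "d"), (3, "p")],
    [(2, "d"), (4, "p")],
]
TOY_OUTLET_FRACTIONS = {3: (0.5, "upper"), 4: (0.5, "lower")}
# The toy loop is sized for a cerebral-scale flow, not a whole-body cardiac
# output: its heart and venous blocks are scaled so it carries ~850 mL/min.
TOY_CO_REF = 20.0    # mL/s
TOY_BODY_BLOCKS = {
    "upper": {"R": 0.7, "L": 5.0e-4, "C": 4.0},
    "lower": {"R": 0.7, "L": 5.0e-4, "C": 5.0},
}
TOY_HEART = {
    "E_max_lv": 8.0,
    "E_min_lv": 0.25,
    "V0_lv": 1.0,
    "E_max_la": 1.5,
    "E_min_la": 0.9,
    "V0_la": 1.0,
    "Ts_lv": 0.35,
    "t_la": 0.85,
    "Ts_la": 0.15,
    "R_mv": 0.02,
    "R_av": 0.02,
    "cardiac_period": 1.0,
}
TOY_COW_OUTLETS = [3]
TOY_COW_INLETS = [1]
TOY_CEREBRAL_IDS = [1, 2, 3, 4]
TOY_STENOSIS_HOSTS = {"left": 1}
TOY_MAP_SEGMENT = 0
TOY_INLET_SEGMENT = 0
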