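"""Default analysis configuration: the canonical variable pairings.

The shipped battery covers the four hypothesis families — developmental
midpoints against mean climate and aridity, within-species minima against
climate minima, hatching time against larval period, traits against genome
size — plus the matched-locality variant, 17 regressions in all; and the
eight variables screened for evolutionary model fit and phylogenetic
signal.
"""

#: (response, predictor) pairs for the PGLS battery.
DEFAULT_PGLS_PAIRS = [
    ("midpoint_larval_period", "bio12_mean"),
    ("midpoint_larval_period", "bio16_mean"),
    ("midpoint_larval_period", "bio15_mean"),
    ("midpoint_larval_period", "logQ"),
    ("midpoint_hatching_time", "bio12_mean"),
    ("midpoint_hatching_time", "bio16_mean"),
    ("midpoint_hatching_time", "bio15_mean"),
    ("midpoint_hatching_time", "logQ"),
    ("minimum_larval_period", "bio12_min"),
    ("minimum_hatching_time", "bio12_min"),
    ("larval_period_matched", "annual_precip_matched"),
    ("midpoint_hatching_time", "midpoint_larval_period"),
    ("minimum_hatching_time", "minimum_larval_period"),
    ("midpoint_larval_period", "genome_size"),
    ("minimum_larval_period", "genome_size"),
    ("midpoint_hatching_time", "genome_size"),
    ("minimum_hatching_time", "genome_size"),
]

#: Variables screened for phylogenetic signal (and for model selection).
DEFAULT_SIGNAL_VARIABLES = [
    "bio12_mean",
    "bio16_mean",
    "bio15_mean",
    "logQ",
    "bio12_min",
    "midpoint_larval_period",
    "midpoint_hatching_time",
    "genome_size",
]

DEFAULT_MODEL_VARIABLES = list(DEFAULT_SIGNAL_VARIABLES)

#: Default elevation bounds (m) for locality vetting.
DEFAULT_ELEVATION_RANGE = (0.0, 3000.0)
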