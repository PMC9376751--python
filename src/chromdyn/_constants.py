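"""Shared vocabulary: histone marks and collapsed chromatin-state categories."""

# Canonical mark order used throughout (columns of every presence matrix).
MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3")

# Collapsed functional categories, listed in tie-break priority order:
# the more information-rich annotation wins a modal tie.
CATEGORIES = ("promoter", "enhancer", "heterochromatin", "repressed", "quiescent")

CATEGORY_PRIORITY = {cat: i for i, cat in enumerate(CATEGORIES)}

# Probability clamp used for Bernoulli emissions so log-likelihoods stay finite.
PROB_EPS = 1e-6
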