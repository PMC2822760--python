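"""Closed vocabularies for sample annotation.

Disease-stage classes follow the CML staging used throughout the package:
chronic phase (CP), accelerated phase (AP), lymphoid / myeloid / mixed
blast crisis (BCL / BCM / BCmix), unclassified, and disease-free controls.
"""

SAMPLE_CLASSES = ("CP", "AP", "BCL", "BCM", "BCmix", "unclassified", "control")

#: classes carrying the lymphoid-lineage signature under study
LYMPHOID_CLASSES = frozenset({"BCL", "BCmix"})

SEXES = ("M", "F", "unknown")
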