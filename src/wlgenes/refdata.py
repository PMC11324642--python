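"""Worked-example reference data.

Gene panels and pairwise differential-correlation results from a published
meta-analysis of cucumber waterlogging-stress transcriptomes (18 control and
18 stress samples pooled from three studies).  These printed tables serve as
fixed inputs for worked examples: the attribute-weighting gene lists at the
0.90 cut-off, the genes selected by L1-penalized logistic regression, and the
top ten differentially correlated gene pairs with their per-condition
Pearson correlations.
"""

from __future__ import annotations

#: per-condition sample count of the pooled design
N_PER_CONDITION = 18

#: (gene id, weight) per attribute-weighting method, cut-off 0.90
WEIGHT_TABLES: dict[str, list[tuple[str, float]]] = {
    "correlation": [
        ("LOC101213801", 1.0),
        ("LOC101210665", 0.981792),
        ("LOC101205805", 0.976468),
        ("LOC101217277", 0.965222),
        ("LOC101213872", 0.961903),
        ("LOC101222503", 0.95507),
        ("LOC101206239", 0.950225),
        ("LOC101206201", 0.947782),
        ("LOC101212424", 0.946504),
        ("LOC101212625", 0.946377),
        ("LOC101203084", 0.936201),
        ("LOC101204590", 0.929242),
        ("LOC101210747", 0.921718),
        ("LOC101214385", 0.919868),
        ("LOC101213580", 0.9143),
        ("LOC116403322", 0.91381),
        ("LOC101205431", 0.913398),
        ("LOC101210491", 0.903276),
        ("LOC105435194", 0.902187),
        ("LOC101204309", 0.901909),
        ("LOC101205898", 0.900742),
    ],
    "svm": [
        ("WRKY34", 1.0),
        ("LOC105435136", 0.955122),
        ("LOC101222803", 0.929876),
        ("LOC101213580", 0.927133),
        ("LOC101212625", 0.926384),
        ("LOC101206142", 0.922183),
        ("LOC101223041", 0.908447),
        ("LOC101202985", 0.908386),
        ("LOC101207749", 0.905523),
        ("LOC116406191", 0.902036),
    ],
    "uncertainty": [
        ("LOC101221250", 1.0),
        ("LOC101209599", 0.956375),
        ("LOC101216320", 0.931761),
        ("LOC101206172", 0.910819),
    ],
    "relief": [
        ("LOC101213801", 1.0),
        ("LOC101205971", 0.964735),
        ("LOC101214385", 0.925444),
        ("LOC101203449", 0.924483),
    ],
}

#: genes with nonzero coefficients at lambda.1se in the L1 logistic fit
LASSO_GENES: list[str] = [
    "LOC101212625",
    "LOC101213580",
    "LOC101213801",
    "LOC101222503",
    "LOC101205805",
    "LOC101205000",
    "LOC101203084",
    "LOC101214385",
    "LOC101210491",
    "LOC101206239",
    "LOC101210665",
    "LOC101205431",
    "LOC101206142",
]

#: top ten differentially correlated pairs: gene1, gene2, control r, control
#: p, stress r, stress p, printed dz, printed p_diff, printed class
TOP_PAIRS: list[dict] = [
    dict(gene1="LOC101209599", gene2="LOC101221250", control_cor=-0.00583, control_pVal=0.981689,
         stress_cor=0.985479, stress_pVal=9.50e-14, zScoreDiff=6.750255, pValDiff=1.48e-11, classes="0/+"),
    dict(gene1="LOC101209599", gene2="LOC101216320", control_cor=-0.28072, control_pVal=0.259164,
         stress_cor=0.971161, stress_pVal=2.20e-11, zScoreDiff=6.574823, pValDiff=4.87e-11, classes="0/+"),
    dict(gene1="LOC101205971", gene2="LOC105435136", control_cor=-0.71511, control_pVal=0.00085,
         stress_cor=0.807402, stress_pVal=5.10e-05, zScoreDiff=5.524036, pValDiff=3.31e-08, classes="-/+"),
    dict(gene1="LOC101204590", gene2="LOC101207749", control_cor=0.708786, control_pVal=0.000991,
         stress_cor=-0.8021, stress_pVal=6.22e-05, zScoreDiff=-5.44772, pValDiff=5.10e-08, classes="+/-"),
    dict(gene1="LOC101216320", gene2="LOC101221250", control_cor=0.392644, control_pVal=0.107014,
         stress_cor=0.983571, stress_pVal=2.54e-13, zScoreDiff=5.427623, pValDiff=5.71e-08, classes="0/+"),
    dict(gene1="LOC101205805", gene2="LOC101217277", control_cor=-0.46192, control_pVal=0.053628,
         stress_cor=0.88249, stress_pVal=1.26e-06, zScoreDiff=5.166829, pValDiff=2.38e-07, classes="0/+"),
    dict(gene1="LOC101206172", gene2="LOC101209599", control_cor=0.010636, control_pVal=0.966589,
         stress_cor=0.950915, stress_pVal=1.45e-09, zScoreDiff=5.013351, pValDiff=5.35e-07, classes="0/+"),
    dict(gene1="LOC101203084", gene2="LOC101206142", control_cor=-0.36789, control_pVal=0.133089,
         stress_cor=0.893961, stress_pVal=5.74e-07, zScoreDiff=5.004244, pValDiff=5.61e-07, classes="0/+"),
    dict(gene1="LOC101204590", gene2="LOC101221250", control_cor=-0.21779, control_pVal=0.385305,
         stress_cor=0.916726, stress_pVal=8.93e-08, zScoreDiff=4.900632, pValDiff=9.55e-07, classes="0/+"),
    dict(gene1="LOC101203449", gene2="LOC101216320", control_cor=0.922398, control_pVal=5.17e-08,
         stress_cor=-0.16899, stress_pVal=0.502642, zScoreDiff=-4.86239, pValDiff=1.16e-06, classes="+/0"),
]

#: the 13 genes appearing in the top ten pairs
TOP_PAIR_GENES: list[str] = [
    "LOC101203084",
    "LOC101205805",
    "LOC101206142",
    "LOC101217277",
    "LOC101204590",
    "LOC101216320",
    "LOC101206172",
    "LOC101209599",
    "LOC101221250",
    "LOC101203449",
    "LOC101205971",
    "LOC105435136",
    "LOC101207749",
]


def method_gene_sets() -> dict[str, set[str]]:
    """Gene-id sets per weighting method."""
    return {m: {g for g, _ in rows} for m, rows in WEIGHT_TABLES.items()}
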