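"""AAL-90 region labels for the FDG-PET feature vector.

The 90 non-cerebellar cortical and subcortical regions of the automated
anatomical labeling (AAL) atlas, in conventional atlas order with left/right
hemisphere interleaved. These are the default names of the regional
pons-normalized FDG SUVr features.
"""

_BASE = [
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
]

#: The 90 AAL region names, left/right interleaved (atlas order).
AAL90: list[str] = [f"{name}_{hemi}" for name in _BASE for hemi in ("L", "R")]

#: Default set of regions carrying the amyloid-status hypometabolism signal in
#: synthetic cohorts: a small AD-vulnerable temporoparietal/limbic network
#: (posterior cingulate, angular gyrus, precuneus, medial temporal structures).
DEFAULT_SIGNAL_REGIONS: tuple[int, ...] = tuple(
    AAL90.index(name)
    for name in (
        "Cingulum_Post_L",
        "Cingulum_Post_R",
        "Angular_L",
        "Angular_R",
        "Precuneus_L",
        "Precuneus_R",
        "Hippocampus_L",
        "Amygdala_R",
        "Temporal_Mid_L",
        "Temporal_Mid_R",
    )
)

assert len(AAL90) == 90
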