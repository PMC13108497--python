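label	network
7Networks_LH_Vis_1	visual
7Networks_LH_Vis_2	visual
7Networks_LH_Vis_3	visual
7Networks_LH_Vis_4	visual
7Networks_LH_Vis_5	visual
7Networks_LH_Vis_6	visual
7Networks_LH_Vis_7	visual
7Networks_LH_Vis_8	visual
7Networks_LH_SomMot_1	somatomotor
7Networks_LH_SomMot_2	somatomotor
7Networks_LH_SomMot_3	somatomotor
7Networks_LH_SomMot_4	somatomotor
7Networks_LH_SomMot_5	somatomotor
7Networks_LH_SomMot_6	somatomotor
7Networks_LH_SomMot_7	somatomotor
7Networks_LH_SomMot_8	somatomotor
7Networks_LH_DorsAttn_1	dorsal_attention
7Networks_LH_DorsAttn_2	dorsal_attention
7Networks_LH_DorsAttn_3	dorsal_attention
7Networks_LH_DorsAttn_4	dorsal_attention
7Networks_LH_DorsAttn_5	dorsal_attention
7Networks_LH_DorsAttn_6	dorsal_attention
7Networks_LH_DorsAttn_7	dorsal_attention
7Networks_LH_SalVentAttn_1	ventral_attention
7Networks_LH_SalVentAttn_2	ventral_attention
7Networks_LH_SalVentAttn_3	ventral_attention
7Networks_LH_SalVentAttn_4	ventral_attention
7Networks_LH_SalVentAttn_5	ventral_attention
7Networks_LH_SalVentAttn_6	ventral_attention
7Networks_LH_SalVentAttn_7	ventral_attention
7Networks_LH_Limbic_1	limbic
7Networks_LH_Limbic_2	limbic
7Networks_LH_Limbic_3	limbic
7Networks_LH_Limbic_4	limbic
7Networks_LH_Limbic_5	limbic
7Networks_LH_Cont_1	frontoparietal
7Networks_LH_Cont_2	frontoparietal
7Networks_LH_Cont_3	frontoparietal
7Networks_LH_Cont_4	frontoparietal
7Networks_LH_Cont_5	frontoparietal
7Networks_LH_Cont_6	frontoparietal
7Networks_LH_Cont_7	frontoparietal
7Networks_LH_Default_1	default_mode
7Networks_LH_Default_2	default_mode
7Networks_LH_Default_3	default_mode
7Networks_LH_Default_4	default_mode
7Networks_LH_Default_5	default_mode
7Networks_LH_Default_6	default_mode
7Networks_LH_Default_7	default_mode
7Networks_LH_Default_8	default_mode
7Networks_RH_Vis_1	visual
7Networks_RH_Vis_2	visual
7Networks_RH_Vis_3	visual
7Networks_RH_Vis_4	visual
7Networks_RH_Vis_5	visual
7Networks_RH_Vis_6	visual
7Networks_RH_Vis_7	visual
7Networks_RH_Vis_8	visual
7Networks_RH_SomMot_1	somatomotor
7Networks_RH_SomMot_2	somatomotor
7Networks_RH_SomMot_3	somatomotor
7Networks_RH_SomMot_4	somatomotor
7Networks_RH_SomMot_5	somatomotor
7Networks_RH_SomMot_6	somatomotor
7Networks_RH_SomMot_7	somatomotor
7Networks_RH_SomMot_8	somatomotor
7Networks_RH_DorsAttn_1	dorsal_attention
7Networks_RH_DorsAttn_2	dorsal_attention
7Networks_RH_DorsAttn_3	dorsal_attention
7Networks_RH_DorsAttn_4	dorsal_attention
7Networks_RH_DorsAttn_5	dorsal_attention
7Networks_RH_DorsAttn_6	dorsal_attention
7Networks_RH_DorsAttn_7	dorsal_attention
7Networks_RH_SalVentAttn_1	ventral_attention
7Networks_RH_SalVentAttn_2	ventral_attention
7Networks_RH_SalVentAttn_3	ventral_attention
7Networks_RH_SalVentAttn_4	ventral_attention
7Networks_RH_SalVentAttn_5	ventral_attention
7Networks_RH_SalVentAttn_6	ventral_attention
7Networks_RH_SalVentAttn_7	ventral_attention
7Networks_RH_Limbic_1	limbic
7Networks_RH_Limbic_2	limbic
7Networks_RH_Limbic_3	limbic
7Networks_RH_Limbic_4	limbic
7Networks_RH_Limbic_5	limbic
7Networks_RH_Cont_1	frontoparietal
7Networks_RH_Cont_2	frontoparietal
7Networks_RH_Cont_3	frontoparietal
7Networks_RH_Cont_4	frontoparietal
7Networks_RH_Cont_5	frontoparietal
7Networks_RH_Cont_6	frontoparietal
7Networks_RH_Cont_7	frontoparietal
7Networks_RH_Default_1	default_mode
7Networks_RH_Default_2	default_mode
7Networks_RH_Default_3	default_mode
7Networks_RH_Default_4	default_mode
7Networks_RH_Default_5	default_mode
7Networks_RH_Default_6	default_mode
7Networks_RH_Default_7	default_mode
7Networks_RH_Default_8	default_mode
LH_Thalamus	subcortical
LH_Caudate	subcortical
LH_Putamen	subcortical
LH_Pallidum	subcortical
LH_Hippocampus	subcortical
LH_Amygdala	subcortical
LH_Accumbens	subcortical
RH_Thalamus	subcortical
RH_Caudate	subcortical
RH_Putamen	subcortical
RH_Pallidum	subcortical
RH_Hippocampus	subcortical
RH_Amygdala	subcortical
RH_Accumbens	subcortical
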