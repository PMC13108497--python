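label	network
BNA_LH_Vis_1	visual
BNA_LH_Vis_2	visual
BNA_LH_Vis_3	visual
BNA_LH_Vis_4	visual
BNA_LH_Vis_5	visual
BNA_LH_Vis_6	visual
BNA_LH_Vis_7	visual
BNA_LH_Vis_8	visual
BNA_LH_Vis_9	visual
BNA_LH_Vis_10	visual
BNA_LH_Vis_11	visual
BNA_LH_Vis_12	visual
BNA_LH_Vis_13	visual
BNA_LH_Vis_14	visual
BNA_LH_Vis_15	visual
BNA_LH_SomMot_1	somatomotor
BNA_LH_SomMot_2	somatomotor
BNA_LH_SomMot_3	somatomotor
BNA_LH_SomMot_4	somatomotor
BNA_LH_SomMot_5	somatomotor
BNA_LH_SomMot_6	somatomotor
BNA_LH_SomMot_7	somatomotor
BNA_LH_SomMot_8	somatomotor
BNA_LH_SomMot_9	somatomotor
BNA_LH_SomMot_10	somatomotor
BNA_LH_SomMot_11	somatomotor
BNA_LH_SomMot_12	somatomotor
BNA_LH_SomMot_13	somatomotor
BNA_LH_SomMot_14	somatomotor
BNA_LH_SomMot_15	somatomotor
BNA_LH_SomMot_16	somatomotor
BNA_LH_DorsAttn_1	dorsal_attention
BNA_LH_DorsAttn_2	dorsal_attention
BNA_LH_DorsAttn_3	dorsal_attention
BNA_LH_DorsAttn_4	dorsal_attention
BNA_LH_DorsAttn_5	dorsal_attention
BNA_LH_DorsAttn_6	dorsal_attention
BNA_LH_DorsAttn_7	dorsal_attention
BNA_LH_DorsAttn_8	dorsal_attention
BNA_LH_DorsAttn_9	dorsal_attention
BNA_LH_DorsAttn_10	dorsal_attention
BNA_LH_DorsAttn_11	dorsal_attention
BNA_LH_DorsAttn_12	dorsal_attention
BNA_LH_DorsAttn_13	dorsal_attention
BNA_LH_DorsAttn_14	dorsal_attention
BNA_LH_DorsAttn_15	dorsal_attention
BNA_LH_VentAttn_1	ventral_attention
BNA_LH_VentAttn_2	ventral_attention
BNA_LH_VentAttn_3	ventral_attention
BNA_LH_VentAttn_4	ventral_attention
BNA_LH_VentAttn_5	ventral_attention
BNA_LH_VentAttn_6	ventral_attention
BNA_LH_VentAttn_7	ventral_attention
BNA_LH_VentAttn_8	ventral_attention
BNA_LH_VentAttn_9	ventral_attention
BNA_LH_VentAttn_10	ventral_attention
BNA_LH_VentAttn_11	ventral_attention
BNA_LH_VentAttn_12	ventral_attention
BNA_LH_VentAttn_13	ventral_attention
BNA_LH_VentAttn_14	ventral_attention
BNA_LH_VentAttn_15	ventral_attention
BNA_LH_Limbic_1	limbic
BNA_LH_Limbic_2	limbic
BNA_LH_Limbic_3	limbic
BNA_LH_Limbic_4	limbic
BNA_LH_Limbic_5	limbic
BNA_LH_Limbic_6	limbic
BNA_LH_Limbic_7	limbic
BNA_LH_Limbic_8	limbic
BNA_LH_Limbic_9	limbic
BNA_LH_Limbic_10	limbic
BNA_LH_Limbic_11	limbic
BNA_LH_Limbic_12	limbic
BNA_LH_Limbic_13	limbic
BNA_LH_Limbic_14	limbic
BNA_LH_Cont_1	frontoparietal
BNA_LH_Cont_2	frontoparietal
BNA_LH_Cont_3	frontoparietal
BNA_LH_Cont_4	frontoparietal
BNA_LH_Cont_5	frontoparietal
BNA_LH_Cont_6	frontoparietal
BNA_LH_Cont_7	frontoparietal
BNA_LH_Cont_8	frontoparietal
BNA_LH_Cont_9	frontoparietal
BNA_LH_Cont_10	frontoparietal
BNA_LH_Cont_11	frontoparietal
BNA_LH_Cont_12	frontoparietal
BNA_LH_Cont_13	frontoparietal
BNA_LH_Cont_14	frontoparietal
BNA_LH_Cont_15	frontoparietal
BNA_LH_Default_1	default_mode
BNA_LH_Default_2	default_mode
BNA_LH_Default_3	default_mode
BNA_LH_Default_4	default_mode
BNA_LH_Default_5	default_mode
BNA_LH_Default_6	default_mode
BNA_LH_Default_7	default_mode
BNA_LH_Default_8	default_mode
BNA_LH_Default_9	default_mode
BNA_LH_Default_10	default_mode
BNA_LH_Default_11	default_mode
BNA_LH_Default_12	default_mode
BNA_LH_Default_13	default_mode
BNA_LH_Default_14	default_mode
BNA_LH_Default_15	default_mode
BNA_RH_Vis_1	visual
BNA_RH_Vis_2	visual
BNA_RH_Vis_3	visual
BNA_RH_Vis_4	visual
BNA_RH_Vis_5	visual
BNA_RH_Vis_6	visual
BNA_RH_Vis_7	visual
BNA_RH_Vis_8	visual
BNA_RH_Vis_9	visual
BNA_RH_Vis_10	visual
BNA_RH_Vis_11	visual
BNA_RH_Vis_12	visual
BNA_RH_Vis_13	visual
BNA_RH_Vis_14	visual
BNA_RH_Vis_15	visual
BNA_RH_SomMot_1	somatomotor
BNA_RH_SomMot_2	somatomotor
BNA_RH_SomMot_3	somatomotor
BNA_RH_SomMot_4	somatomotor
BNA_RH_SomMot_5	somatomotor
BNA_RH_SomMot_6	somatomotor
BNA_RH_SomMot_7	somatomotor
BNA_RH_SomMot_8	somatomotor
BNA_RH_SomMot_9	somatomotor
BNA_RH_SomMot_10	somatomotor
BNA_RH_SomMot_11	somatomotor
BNA_RH_SomMot_12	somatomotor
BNA_RH_SomMot_13	somatomotor
BNA_RH_SomMot_14	somatomotor
BNA_RH_SomMot_15	somatomotor
BNA_RH_SomMot_16	somatomotor
BNA_RH_DorsAttn_1	dorsal_attention
BNA_RH_DorsAttn_2	dorsal_attention
BNA_RH_DorsAttn_3	dorsal_attention
BNA_RH_DorsAttn_4	dorsal_attention
BNA_RH_DorsAttn_5	dorsal_attention
BNA_RH_DorsAttn_6	dorsal_attention
BNA_RH_DorsAttn_7	dorsal_attention
BNA_RH_DorsAttn_8	dorsal_attention
BNA_RH_DorsAttn_9	dorsal_attention
BNA_RH_DorsAttn_10	dorsal_attention
BNA_RH_DorsAttn_11	dorsal_attention
BNA_RH_DorsAttn_12	dorsal_attention
BNA_RH_DorsAttn_13	dorsal_attention
BNA_RH_DorsAttn_14	dorsal_attention
BNA_RH_DorsAttn_15	dorsal_attention
BNA_RH_VentAttn_1	ventral_attention
BNA_RH_VentAttn_2	ventral_attention
BNA_RH_VentAttn_3	ventral_attention
BNA_RH_VentAttn_4	ventral_attention
BNA_RH_VentAttn_5	ventral_attention
BNA_RH_VentAttn_6	ventral_attention
BNA_RH_VentAttn_7	ventral_attention
BNA_RH_VentAttn_8	ventral_attention
BNA_RH_VentAttn_9	ventral_attention
BNA_RH_VentAttn_10	ventral_attention
BNA_RH_VentAttn_11	ventral_attention
BNA_RH_VentAttn_12	ventral_attention
BNA_RH_VentAttn_13	ventral_attention
BNA_RH_VentAttn_14	ventral_attention
BNA_RH_VentAttn_15	ventral_attention
BNA_RH_Limbic_1	limbic
BNA_RH_Limbic_2	limbic
BNA_RH_Limbic_3	limbic
BNA_RH_Limbic_4	limbic
BNA_RH_Limbic_5	limbic
BNA_RH_Limbic_6	limbic
BNA_RH_Limbic_7	limbic
BNA_RH_Limbic_8	limbic
BNA_RH_Limbic_9	limbic
BNA_RH_Limbic_10	limbic
BNA_RH_Limbic_11	limbic
BNA_RH_Limbic_12	limbic
BNA_RH_Limbic_13	limbic
BNA_RH_Limbic_14	limbic
BNA_RH_Cont_1	frontoparietal
BNA_RH_Cont_2	frontoparietal
BNA_RH_Cont_3	frontoparietal
BNA_RH_Cont_4	frontoparietal
BNA_RH_Cont_5	frontoparietal
BNA_RH_Cont_6	frontoparietal
BNA_RH_Cont_7	frontoparietal
BNA_RH_Cont_8	frontoparietal
BNA_RH_Cont_9	frontoparietal
BNA_RH_Cont_10	frontoparietal
BNA_RH_Cont_11	frontoparietal
BNA_RH_Cont_12	frontoparietal
BNA_RH_Cont_13	frontoparietal
BNA_RH_Cont_14	frontoparietal
BNA_RH_Cont_15	frontoparietal
BNA_RH_Default_1	default_mode
BNA_RH_Default_2	default_mode
BNA_RH_Default_3	default_mode
BNA_RH_Default_4	default_mode
BNA_RH_Default_5	default_mode
BNA_RH_Default_6	default_mode
BNA_RH_Default_7	default_mode
BNA_RH_Default_8	default_mode
BNA_RH_Default_9	default_mode
BNA_RH_Default_10	default_mode
BNA_RH_Default_11	default_mode
BNA_RH_Default_12	default_mode
BNA_RH_Default_13	default_mode
BNA_RH_Default_14	default_mode
BNA_RH_Default_15	default_mode
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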