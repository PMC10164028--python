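name	network	hemisphere
L_middle_frontal_gyrus_aSal	anterior_salience	L
R_middle_frontal_gyrus_aSal	anterior_salience	R
L_anterior_insula	anterior_salience	L
R_anterior_insula	anterior_salience	R
anterior_cingulate_cortex	anterior_salience	M
L_supplementary_motor_area_aSal	anterior_salience	L
R_supplementary_motor_area_aSal	anterior_salience	R
L_superior_temporal_gyrus	auditory	L
R_superior_temporal_gyrus	auditory	R
medial_geniculate_thalamus	auditory	M
L_caudate	basal_ganglia	L
R_caudate	basal_ganglia	R
L_putamen_pallidum	basal_ganglia	L
R_putamen_pallidum	basal_ganglia	R
pons	basal_ganglia	M
medial_prefrontal_cortex	dorsal_default_mode	M
L_angular_gyrus_dDMN	dorsal_default_mode	L
R_angular_gyrus_dDMN	dorsal_default_mode	R
posterior_cingulate_cortex	dorsal_default_mode	M
L_hippocampus	dorsal_default_mode	L
R_hippocampus	dorsal_default_mode	R
midcingulate_cortex	dorsal_default_mode	M
L_thalamus_dDMN	dorsal_default_mode	L
R_thalamus_dDMN	dorsal_default_mode	R
L_middle_temporal_MT	high_visual	L
R_middle_temporal_MT	high_visual	R
L_inferior_frontal_gyrus	language	L
R_inferior_frontal_gyrus	language	R
L_middle_temporal_gyrus	language	L
L_superior_temporal_sulcus	language	L
L_supramarginal_gyrus_lang	language	L
L_angular_gyrus_lang	language	L
R_cerebellum_crus_lang	language	R
L_middle_frontal_gyrus_ECN	left_executive_control	L
L_inferior_parietal_lobule_ECN	left_executive_control	L
L_superior_frontal_gyrus_ECN	left_executive_control	L
L_inferior_temporal_gyrus_ECN	left_executive_control	L
L_thalamus_ECN	left_executive_control	L
R_cerebellum_crus_LECN	left_executive_control	R
L_precuneus	precuneus	L
R_precuneus	precuneus	R
midline_precuneus	precuneus	M
posterior_precuneus_cuneus	precuneus	M
L_calcarine_cortex	primary_visual	L
R_calcarine_cortex	primary_visual	R
L_posterior_insula	posterior_salience	L
R_posterior_insula	posterior_salience	R
L_supramarginal_gyrus_pSal	posterior_salience	L
R_supramarginal_gyrus_pSal	posterior_salience	R
L_precentral_gyrus_pSal	posterior_salience	L
R_precentral_gyrus_pSal	posterior_salience	R
L_thalamus_pSal	posterior_salience	L
R_thalamus_pSal	posterior_salience	R
L_cerebellum_lobule_VI	posterior_salience	L
R_cerebellum_lobule_VI	posterior_salience	R
L_middle_cingulate_pSal	posterior_salience	L
R_middle_cingulate_pSal	posterior_salience	R
R_middle_frontal_gyrus_ECN	right_executive_control	R
R_inferior_parietal_lobule_ECN	right_executive_control	R
R_superior_frontal_gyrus_ECN	right_executive_control	R
R_inferior_temporal_gyrus_ECN	right_executive_control	R
R_thalamus_ECN	right_executive_control	R
L_cerebellum_crus_RECN	right_executive_control	L
L_precentral_gyrus_SM	sensorimotor	L
R_precentral_gyrus_SM	sensorimotor	R
supplementary_motor_area_SM	sensorimotor	M
L_postcentral_gyrus_SM	sensorimotor	L
R_postcentral_gyrus_SM	sensorimotor	R
cerebellar_vermis_SM	sensorimotor	M
L_frontal_eye_field	visuospatial	L
R_frontal_eye_field	visuospatial	R
L_intraparietal_sulcus	visuospatial	L
R_intraparietal_sulcus	visuospatial	R
L_superior_parietal_lobule	visuospatial	L
R_superior_parietal_lobule	visuospatial	R
L_middle_occipital_gyrus	visuospatial	L
R_middle_occipital_gyrus	visuospatial	R
L_inferior_temporal_vis	visuospatial	L
R_inferior_temporal_vis	visuospatial	R
superior_colliculus_vis	visuospatial	M
L_parahippocampal_gyrus	ventral_default_mode	L
R_parahippocampal_gyrus	ventral_default_mode	R
L_retrosplenial_cortex	ventral_default_mode	L
R_retrosplenial_cortex	ventral_default_mode	R
L_middle_occipital_vDMN	ventral_default_mode	L
R_middle_occipital_vDMN	ventral_default_mode	R
L_lateral_parietal_vDMN	ventral_default_mode	L
R_lateral_parietal_vDMN	ventral_default_mode	R
precuneus_vDMN	ventral_default_mode	M
cerebellar_tonsil_vDMN	ventral_default_mode	M
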