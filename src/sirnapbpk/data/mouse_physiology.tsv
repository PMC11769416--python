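# Mouse whole-body physiology for a large-molecule circulation model.
# Reference animal: 0.025 kg C57BL/6-like mouse.
# Provenance: curated from published rodent physiology compilations used by
# whole-body PBPK models of proteins/large molecules (organ weights and
# regional plasma flows after Brown et al. 1997 Toxicol Ind Health 13:407;
# vascular/interstitial volume fractions after Shah & Betts 2012 JPKPD 39:67;
# capillary surface areas order-of-magnitude per-gram values from the same
# literature; endosomal fraction fixed at 0.5% of organ volume).
# Pore geometry: two-pore formalism with small/large pore radii 4.4/22.85 nm.
# alpha_large = fraction of transcapillary (lymph) fluid flow passing the
# large-pore system (two-pore literature convention); A0_frac_large =
# fraction of total pore cross-sectional area in large pores (raised in
# fenestrated organs: liver, spleen, kidney).
# A0_dx_cm = total pore cross-section area / effective endothelial thickness,
# the geometric factor multiplying the free diffusion coefficient in the
# permeability-surface-area product (curated as ~2 cm^-1 x SA_cap; liver 20 cm^-1, fenestrated sinusoids).
# species: mouse
# body_weight_ref_kg: 0.025
# hematocrit: 0.45
# GFR_L_per_h: 0.015
# V_venous_plasma_L: 0.00025
# V_arterial_plasma_L: 0.00012
# r_small_nm: 4.4
# r_large_nm: 22.85
organ	V_total_mL	f_vascular	f_interstitial	f_endosomal	Q_plasma_L_per_h	lymph_frac	SA_cap_cm2	A0_dx_cm	A0_frac_large	alpha_large
lung	0.120	0.26	0.19	0.005	0.46000	0.002	36.0	72	0.05	0.042
heart	0.125	0.10	0.10	0.005	0.03948	0.002	62.5	125	0.05	0.042
brain	0.425	0.03	0.18	0.005	0.01974	0.002	63.8	127.6	0.01	0.042
muscle	9.500	0.026	0.12	0.005	0.09511	0.002	665.0	1330	0.05	0.042
bone	2.700	0.04	0.10	0.005	0.07298	0.002	81.0	162	0.05	0.042
skin	4.000	0.02	0.30	0.005	0.03469	0.002	280.0	560	0.05	0.042
fat	1.750	0.01	0.135	0.005	0.02991	0.002	122.5	245	0.05	0.042
stomach	0.110	0.03	0.10	0.005	0.00897	0.002	11.0	22	0.05	0.042
small_intestine	0.720	0.02	0.094	0.005	0.05982	0.002	50.4	100.8	0.05	0.042
large_intestine	0.350	0.02	0.09	0.005	0.01795	0.002	35.0	70	0.05	0.042
spleen	0.085	0.28	0.15	0.005	0.00598	0.002	5.1	10.2	0.20	0.042
pancreas	0.097	0.03	0.12	0.005	0.00598	0.002	9.7	19.4	0.05	0.042
liver	1.370	0.21	0.16	0.005	0.01196	0.002	342.5	6850.0	0.20	0.042
kidney	0.425	0.16	0.20	0.005	0.05443	0.002	148.8	297.6	0.10	0.042
gonads	0.050	0.03	0.20	0.005	0.00299	0.002	5.0	10	0.05	0.042
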