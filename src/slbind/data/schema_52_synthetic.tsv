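# Synthetic stand-in feature schema (52 descriptors), one "name<TAB>unit" per line.
# Names follow the field conventions for interface descriptors ("cms" for
# contact molecular surface, "ifa_" for interface-analyzer metrics, plus
# per-term interface energies in Rosetta energy units). Replace this file
# verbatim with the production descriptor list to change the schema.
cms	A^2
interaction_energy	REU
interface_holes	dimensionless
ifa_dG_separated	REU
ifa_dG_separated_per_dSASA	REU/A^2
ifa_dSASA_int	A^2
ifa_dSASA_hphobic	A^2
ifa_dSASA_polar	A^2
ifa_complex_normalized	REU
ifa_hbond_E_fraction	dimensionless
ifa_hbonds_int	count
ifa_nres_int	count
ifa_nres_all	count
ifa_packstat	dimensionless
ifa_per_residue_energy_int	REU
ifa_sc_value	dimensionless
ifa_side1_normalized	REU
ifa_side2_normalized	REU
ifa_side1_score	REU
ifa_side2_score	REU
ifa_complexed_sasa	A^2
ifa_separated_sasa	A^2
ifa_crossterm_interface_energy	REU
ifa_complex_energy	REU
ifa_separated_interface_energy	REU
ifa_total_energy	REU
fa_atr	REU
fa_rep	REU
fa_sol	REU
fa_elec	REU
fa_intra_atr_xover4	REU
fa_intra_rep_xover4	REU
fa_intra_sol_xover4	REU
lk_ball	REU
lk_ball_iso	REU
lk_ball_bridge	REU
lk_ball_bridge_uncpl	REU
omega	REU
rama_prepro	REU
p_aa_pp	REU
pro_close	REU
hbond_sr_bb	REU
hbond_lr_bb	REU
hbond_bb_sc	REU
hbond_sc	REU
dslf_fa13	REU
fa_dun_rot	REU
fa_dun_dev	REU
fa_dun_semi	REU
ref	REU
hxl_tors	REU
total_score	REU
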