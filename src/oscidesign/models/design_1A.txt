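# Minimal budding-yeast Clb/Cdk1 oscillator, mass-action complex kinetics.
# State: free x = Clb5/Cdk1, y = Clb3/Cdk1, z = Clb2/Cdk1, s = Sic1, plus the
# three dynamic ternary complexes c_x, c_y, c_z (k_plus association,
# k_minus dissociation).  delta degrades the Sic1 subunit of a complex
# (releasing the Clb), epsilon degrades the Clb subunit (releasing Sic1).
# Core design: documented interactions only (no Clb PFLs or self-NFLs);
# k_cln lumps Cln/Cdk1-mediated phosphorylation-degradation of free Sic1.
@name design_1A
@species Sic1=s Clb5=x Clb3=y Clb2=z
@peak_order Sic1 Clb5 Clb3 Clb2
x' = v_x + k_minus*c_x + delta*c_x - beta_x*x - gamma_yx*y*x - gamma_zx*z*x - k_plus*x*s
y' = v_y + alpha_xy*x + k_minus*c_y + delta*c_y - beta_y*y - gamma_zy*z*y - k_plus*y*s
z' = v_z + alpha_xz*x + alpha_yz*y + k_minus*c_z + delta*c_z - beta_z*z - k_plus*z*s
s' = v_s + k_minus*c_x + k_minus*c_y + k_minus*c_z + epsilon*c_x + epsilon*c_y + epsilon*c_z - beta_s*s - k_cln*s - k_plus*x*s - k_plus*y*s - k_plus*z*s
c_x' = k_plus*x*s - k_minus*c_x - delta*c_x - epsilon*c_x
c_y' = k_plus*y*s - k_minus*c_y - delta*c_y - epsilon*c_y
c_z' = k_plus*z*s - k_minus*c_z - delta*c_z - epsilon*c_z
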