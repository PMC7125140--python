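# Minimal budding-yeast Clb/Cdk1 oscillator, QSSA core design.
# Free-species state: x = Clb5/Cdk1, y = Clb3/Cdk1, z = Clb2/Cdk1, s = Sic1.
# Ternary Clb/Cdk1/Sic1 complexes are at binding equilibrium (c_i = K_A*i*s);
# delta removes Sic1 from the complex pool, epsilon removes the Clb subunit.
# Reconstructed interaction set: basal synthesis/degradation (v, beta),
# transcriptional activations incl. the linear CLB cascade (alpha_xy, alpha_yz)
# and the Clb3/Clb2 positive feedback loops (alpha_yy, alpha_zz),
# APC-mediated inhibitions (gamma terms).
@name design_3
@species Sic1=s Clb5=x Clb3=y Clb2=z
@peak_order Sic1 Clb5 Clb3 Clb2
x' = v_x - beta_x*x - gamma_yx*y*x - gamma_zx*z*x - epsilon*c_x
y' = v_y + alpha_xy*x + alpha_yy*y - beta_y*y - gamma_yy*y^2 - gamma_zy*z*y - epsilon*c_y
z' = v_z + alpha_xz*x + alpha_yz*y + alpha_zz*z - beta_z*z - gamma_zz*z^2 - epsilon*c_z
s' = v_s - beta_s*s - delta*c_x - delta*c_y - delta*c_z
c_x = K_A*x*s
c_y = K_A*y*s
c_z = K_A*z*s
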