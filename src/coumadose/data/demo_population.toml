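# DEMO population parameter set for the warfarin KPD model.
#
# These values are physiologically plausible placeholders for testing and
# documentation ONLY. They are NOT the published population estimates and
# must NOT be used for patient care: a deployer must transcribe a published,
# validated parameter set into a file with this schema.

provenance = "DEMO — not for clinical use; plausible placeholder values for testing"

[pk]
tv_cl = 0.30   # L/h at the reference covariates
tv_v = 14.0    # L

[pd]
gamma = 2.0
emax = 1.0
mtt1 = 29.0    # h, fast chain
mtt2 = 118.0   # h, slow chain
n_transit = 3
inr_max = 20.0

[pd.edk50]
# dose rate giving half-maximal inhibition, by VKORC1 genotype
units = "mg/day"
"G/G" = 24.0
"A/G" = 17.0
"A/A" = 10.0

[covariates]
ref_weight = 70.0       # kg
ref_age = 50.0          # years
cl_weight_exp = 0.75    # allometric exponent on CL
v_weight_exp = 1.0      # allometric exponent on V
cl_age_slope = 0.002    # per-year exponential decline of CL
edk50_weight_exp = 0.75 # allometric exponent on EDK50 (dose requirement)

[covariates.cyp2c9_cl_mult]
"*1/*1" = 1.00
"*1/*2" = 0.85
"*1/*3" = 0.70
"*2/*2" = 0.60
"*2/*3" = 0.50
"*3/*3" = 0.30

[covariates.cyp2c9_edk50_mult]
"*1/*1" = 1.00
"*1/*2" = 0.85
"*1/*3" = 0.70
"*2/*2" = 0.60
"*2/*3" = 0.45
"*3/*3" = 0.25

[variability]
omega_k10 = 0.0625    # variance of log-scale BSV on k10 (SD 0.25)
omega_edk50 = 0.09    # variance of log-scale BSV on EDK50 (SD 0.30)
sigma_add = 0.15      # additive residual SD on the INR scale
residual_model = "additive"
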