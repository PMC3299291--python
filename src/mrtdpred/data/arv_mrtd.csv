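name,subset,mrtd,oxid_hl,p_bd,log_bio_hl,alogp,asol,mw
Acyclovir,train,13.30,0.135,0.5475,-2.2874,-1.45,8.65,225.21
Ancitabine,train,20.00,0.139,0.2005,-2.418,-2.62,3.20,225.21
Delaviridine,train,6.67,0.034,0.0014,-2.3428,2.77,0.086,456.57
Didanosine,train,6.67,0.140,0.5085,-1.9956,-1.26,6.43,236.23
Famciclovir,train,25.00,0.051,0.991,-3.6235,0.13,1.32,321.38
Foscarnet,train,120.00,13.37,0.772,-2.4547,-1.63,16.76,126.01
Indinavir,train,16.70,0.038,0.0501,-4.6478,3.26,0.048,613.81
Lofexidine,train,0.040,0.123,0.0792,0.9861,3.31,0.15,259.14
Lamivudine,train,5.00,0.06,0.0719,-3.9261,-1.29,2.76,229.26
Rimantadine,train,3.33,0.171,0.4624,0.4539,3.28,0.009,179.31
Ribavirin,train,200.00,0.264,0.8963,-2.8715,-1.92,33.17,244.21
Valacyclovir,train,50.00,0.044,0.944,-3.3309,-1.03,1.49,326.41
Zalcitibine,train,0.0375,0.096,0.0909,-3.5083,-1.29,7.05,211.22
Zanamivir,train,0.333,0.038,0.8247,-4.4141,-2.29,1.49,332.32
Zidovudine,train,10.00,0.139,0.0432,-3.0445,-0.1,16.35,267.28
Saquinavir,train,33.330,0.052,0.9780,-3.9394,4.04,0.002,670.84
Darunavir,train,53.00,0.094,0.0001,-1.8175,1.76,0.067,547.66
Tipranavir,train,16.70,0.043,0.0000,-0.0265,5.71,0.0002,602.66
Ritonavir,train,20.00,0.105,0.9488,-4.61,4.24,0.0012,720.94
Maraviroc,train,20.00,0.129,0.0700,-0.2247,4.3,0.0106,513.66
Tenofovir,train,10.00,0.048,0.0016,-3.0098,-1.51,1.87,287.21
Nelfinavir,train,25.00,0.055,0.6868,-1.6709,6.00,0.0002,567.78
Stavudine,train,1.333,0.088,0.0768,-3.082,-0.8,40.51,224.21
Abacavir,test,10.00,0.040,0.0229,-2.1757,0.61,1.21,286.38
Emtricitabine,test,4.00,0.08,0.0566,-3.7784,-0.8,2.00,247.28
Raltegravir,test,30.07,0.094,0.0006,-2.6157,1.7,0.095,444.47
Nevirapine,test,3.000,0.167,0.0473,-3.7336,1.75,0.10,266.33
Efavirenz,test,10.10,0.254,0.0001,0.1111,3.88,0.008,315.67
Fosamprenavir,test,46.70,0.067,0.0007,-2.4135,0.84,0.068,585.68
Atazanavir,test,5.35,0.109,0.0202,-3.4392,4.37,0.003,704.96
Lopiravir,test,53.33,0.103,0.9933,-3.3281,4.07,0.002,614.86
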