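group,salt,molality,n_water,n_salt,density,viscosity,sigma_eh,sigma_ne,sigma_ne_yh,excluded_from_ci,target_id
Madrid,NaCl,0,4440,0,997.3,0.85,0,0,0,False,
Delft,NaCl,0,1000,0,997.9,0.82,0,0,0,False,
Madrid,NaCl,1,4440,80,1035.2,0.97,7.8,9.7,10.6,False,t1
Delft,NaCl,1,1000,18,1034.8,0.929,8.7,9.6,11.2,False,t3
Delft,NaCl,1,555,10,1034.9,0.93,8.7,9.6,11.5,False,t4
Madrid,NaCl,2,4440,160,1070.3,1.12,14.0,17.3,18.9,False,
Delft,NaCl,2,1000,36,1069.9,1.07,14.3,17.3,19.9,False,
Delft,NaCl,2,555,20,1070.1,1.08,13.8,16.7,19.9,False,
Madrid,NaCl,4,4440,320,1135.4,1.44,20.1,27.3,29.6,False,
Delft,NaCl,4,1000,72,1134.92,1.37,20.4,27.4,31.3,False,
Delft,NaCl,4,555,40,1135.31,1.32,21.6,26.5,31.4,False,
Madrid,NaCl,6,4440,480,1194.5,1.79,22.2,32.6,35.2,False,t2
Delft,NaCl,6,1000,108,1194.0,1.69,23.8,32.53,37.04,False,
Delft,NaCl,6,555,60,1194.0,1.69,23.8,32.2,37.7,False,
Madrid,KCl,0,4440,0,997.3,0.85,0,0,0,False,
Delft,KCl,0,1000,0,997.9,0.82,0,0,0,False,
Madrid,KCl,2,4440,160,1081.1,0.95,20.4,24.0,25.8,False,t5
Delft,KCl,2,1000,36,1080.6,0.91,20.8,23.7,26.7,False,t6
Delft,KCl,2,555,20,1080.8,0.92,20.8,22.8,26.5,False,
Madrid,KCl,4,4440,320,1152.3,1.03,32.5,40.5,43.1,True,
Delft,KCl,4,1000,72,1151.60,1.00,32.9,39.7,44.8,False,
Delft,KCl,4,555,40,1151.81,0.99,32.4,38.8,45.1,False,
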