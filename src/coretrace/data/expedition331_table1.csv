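hole,section,coring_system,depth_mbsf,lithology,ms_interior,ms_exterior,pft_interior,pft_exterior,pcr_amplified,contamination_pct
C0013B,1T-1,EPCS,0.6,Hydrothermal clay,N.D.,5.8e2,,,,
C0013B,1T-1,EPCS,1.0,"Hydrothermal gravel, clast-supported",N.D.,4.2e2,,,+,0
C0013D,1H-1,HPCS,3.1,Sulfidic sand,1.7e4,6.6e4,,,+,52
C0013D,1H-2,HPCS,4.3,"Hydrothermal grit, clast-supported",5.8e2,8.4e4,,,,
C0013D,1H-4,HPCS,6.9,"Hydrothermal gravel, matrix-supported",N.D.,1.2e4,,,,
C0013D,1H-5,HPCS,7.7,"Hydrothermal gravel, matrix-supported",N.D.,N.D.,,,,
C0013E,1H-2,HPCS,0.2,Sulfidic sand,N.D.,3.9e2,,,,
C0013E,1H-2,HPCS,1.1,Sulfidic sand,N.D.,N.D.,,,,
C0013E,1H-4,HPCS,2.4,Sulfidic sand,N.D.,N.D.,,,,
C0013E,1H-5,HPCS,4.3,Hydrothermal clay,N.D.,N.D.,,,,
C0013E,1H-6,HPCS,5.4,"Hydrothermal grit, matrix-supported",N.D.,,,,,
C0013E,5H-1,HPCS,17.0,Hydrothermal clay,N.D.,,,,,
C0013F,1H-2,HPCS,0.2,Sulfidic sand,N.D.,N.D.,4.3e-6,3.3e-3,,
C0013F,1H-3,HPCS,1.4,Hydrothermal clay,N.D.,1.5e2,,,,
C0013F,1H-5,HPCS,3.1,Hydrothermal clay,N.D.,N.D.,N.D.,1.0e-5,,
C0014B,1H-1,HPCS,0.3,Clay,N.D.,N.D.,,,+,0
C0014B,1H-1,HPCS,1.1,Clay,N.D.,N.D.,1.0e-5,5.3e-5,+,0
C0014B,1H-2,HPCS,2.4,Clay,N.D.,N.D.,N.D.,1.3e-5,+,0
C0014B,2H-3,HPCS,8.5,"Pumiceous grit, clast-supported",N.D.,3.6e4,N.D.,5.3e-5,+,0
C0014B,2H-7,HPCS,12.2,Hydrothermal clay,1.8e2,N.D.,,,+,0
C0014B,2H-10,HPCS,14.3,Hydrothermal clay,N.D.,N.D.,N.D.,8.2e-6,+,0
C0014B,3H-2,HPCS,17.2,Hydrothermal clay,N.D.,2.2e5,,,,
C0014B,3H-5,HPCS,19.2,Hydrothermal clay,N.D.,6.3e3,1.3e-6,7.8e-5,,
C0014B,3H-9,HPCS,23.2,Hydrothermal clay,N.D.,N.D.,8.0e-7,9.9e-6,,
C0014B,4H-2,HPCS,26.2,Hydrothermal clay,N.D.,5.8e2,,,,
C0014B,4H-3,HPCS,27.5,"Hydrothermal gravel, matrix-supported",N.D.,N.D.,N.D.,3.9e-6,,
C0014B,4H-4,HPCS,28.8,"Hydrothermal gravel, matrix-supported",N.D.,N.D.,,,,
C0014B,4H-6,HPCS,31.1,Hydrothermal clay,N.D.,N.D.,,,,
C0014B,4H-7,HPCS,32.6,Hydrothermal clay,N.D.,N.D.,,,,
C0014B,4H-8,HPCS,33.7,Hydrothermal clay,N.D.,N.D.,N.D.,N.D.,,
C0014B,5H-12,HPCS,40.6,Hydrothermal clay,N.D.,N.D.,2.6e-5,6.0e-4,,
C0014B,5H-14,HPCS,42.3,"Hydrothermal gravel, matrix-supported",N.D.,N.D.,,,,
C0014B,5H-15,HPCS,43.8,"Hydrothermal gravel, matrix-supported",N.D.,N.D.,N.D.,1.5e-3,,
C0014D,1H-1,HPCS,0.2,Clay,N.D.,N.D.,N.D.,N.D.,+,0
C0014D,1H-2,HPCS,2.0,Sandy silt,N.D.,3.6e2,,,+,0
C0014D,1H-3,HPCS,3.1,"Pumiceous gravel, matrix-supported",N.D.,N.D.,2.0e-5,1.9e-6,+,0
C0014D,1H-4,HPCS,4.2,"Pumiceous grit, clast-supported",N.D.,5.5e2,1.3e-5,2.1e-4,+,1
C0014D,2H-1,HPCS,6.7,"Pumiceous gravel, clast-supported",1.4e4,7.7e3,1.0e-4,1.1e-4,+,10
C0014D,2H-2,HPCS,8.6,"Pumiceous gravel, clast-supported",N.D.,N.D.,2.6e-6,1.7e-5,+,0
C0014D,2H-3,HPCS,10.2,"Gradation from clayey hydrothermal sand to pumiceous grit, matrix-supported",N.D.,3.9e2,,,+,0
C0014D,2H-4,HPCS,11.4,Hydrothermal clay,N.D.,1.5e2,N.D.,1.7e-6,+,0
C0014D,2H-6,HPCS,12.8,Hydrothermal clay,N.D.,1.2e3,N.D.,1.7e-6,,
C0014E,1H-3,HPCS,18.5,Hydrothermal clay,N.D.,9.4e3,,,,
C0014E,1H-4,HPCS,19.7,Hydrothermal clay,N.D.,3.1e3,N.D.,5.8e-6,,
C0014E,1H-5,HPCS,20.7,Hydrothermal clay,N.D.,N.D.,,,,
C0014E,1H-6,HPCS,22.1,Hydrothermal clay,N.D.,,N.D.,N.D.,,
C0014E,2H-4,HPCS,27.4,Hydrothermal clay,N.D.,N.D.,,,,
C0014E,2H-5,HPCS,29.1,Hydrothermal clay,N.D.,N.D.,,,,
C0014E,2H-6,HPCS,30.8,"Hydrothermal gravel, matrix-supported",N.D.,N.D.,N.D.,2.5e-5,,
C0014E,2H-7,HPCS,32.0,Hydrothermal clay,N.D.,N.D.,,,,
C0014E,2H-8,HPCS,33.3,Hydrothermal clay,N.D.,N.D.,N.D.,5.6e-5,,
C0014G,1H-1,HPCS,0.3,Clay,N.D.,N.D.,9.6e-7,9.1e-4,+,5
C0014G,1H-2,HPCS,1.8,Silty clay,N.D.,N.D.,,,+,1
C0014G,1H-3,HPCS,3.7,Sandy clay,1.9e2,2.5e3,,,+,4
C0014G,1H-4,HPCS,4.1,"Pumiceous gravel, matrix-supported",N.D.,N.D.,1.5e-6,2.3e-4,+,10
C0014G,1H-5,HPCS,5.9,Hydrothermal clay,N.D.,N.D.,,,+,5
C0014G,1H-6,HPCS,7.8,"Pumiceous gravel, clast-supported",2.9e2,N.D.,,,+,26
C0014G,2H-5,HPCS,15.8,Hydrothermal clay,N.D.,1.5e2,N.D.,N.D.,+,2
C0014G,2H-7,HPCS,17.6,Hydrothermal clay,N.D.,4.4e2,,,,
C0014G,3H-5,HPCS,22.7,Hydrothermal clay,N.D.,N.D.,N.D.,,,
C0014G,3H-8,HPCS,25.3,Hydrothermal clay,N.D.,N.D.,,,,
C0014G,4H-2,HPCS,29.2,Hydrothermal clay,N.D.,N.D.,N.D.,N.D.,,
C0014G,4H-5,HPCS,31.0,Hydrothermal clay,N.D.,N.D.,,,,
C0014G,4H-7,HPCS,32.6,Hydrothermal clay,N.D.,N.D.,,,,
C0014G,4H-9,HPCS,34.6,"Hydrothermal gravel, matrix-supported",4.0e3,3.3e3,,,,
C0014G,4H-10,HPCS,35.6,Hydrothermal clay,N.D.,N.D.,,,,
C0014G,4H-11,HPCS,37.1,Hydrothermal clay,N.D.,1.5e3,,,,
C0014G,5H-3,HPCS,38.1,Hydrothermal clay,N.D.,N.D.,N.D.,1.4e-4,,
C0014G,6H-2,HPCS,47.6,Hydrothermal clay,N.D.,N.D.,,,,
C0014G,6H-3,HPCS,47.8,Hydrothermal clay,N.D.,N.D.,5.8e-7,2.8e-6,,
C0014G,9X-2,ESCS,55.7,"Hydrothermal gravel, matrix-supported",,,3.0e-5,3.9e-4,,
C0014G,12H-3,HPCS,65.4,Hydrothermal clay,N.D.,N.D.,N.D.,1.2e-6,,
C0014G,13T-1,EPCS,67.5,Hydrothermal clay,,,N.D.,,,
C0014G,14T-2,EPCS,71.7,Hydrothermal clay,,,1.0e-6,1.3e-4,,
C0014G,16T-1,EPCS,76.4,Hydrothermal clay,,,1.3e-5,4.3e-6,,
C0014G,17T-2,EPCS,81.2,Hydrothermal clay,,,8.2e-7,8.3e-6,,
C0015B,1H-1,HPCS,0.3,"Pumiceous gravel, matrix-supported",N.D.,N.D.,N.D.,1.3e-6,,
C0015B,1H-3,HPCS,3.4,Mud-supported bioclastic gravel,N.D.,4.4e2,N.D.,3.6e-6,,
C0015B,1H-5,HPCS,5.6,Clay,N.D.,1.8e2,,,,
C0015C,1H-1,HPCS,6.9,Sand,4.4e4,1.5e4,,,,
C0015C,1H-3,HPCS,8.8,Sand,N.D.,1.5e2,1.3e-5,1.7e-5,,
C0017A,1H-1,HPCS,0.7,Clay,N.D.,1.3e3,N.D.,3.4e-5,+,0
C0017A,1H-5,HPCS,6.4,Gradation from silty clay to calcareous sand,N.D.,2.9e3,N.D.,1.1e-4,+,0
C0017B,1H-2,HPCS,10.8,Clay,N.D.,2.5e4,N.D.,1.9e-4,+,0
C0017B,1H-5,HPCS,14.8,Clay,N.D.,2.3e2,N.D.,7.4e-5,+,0
C0017C,1H-2,HPCS,20.1,"Pumiceous gravel, matrix-supported",2.9e2,7.0e4,N.D.,5.1e-5,+,0
C0017C,1H-5,HPCS,24.6,Sandy clay,N.D.,3.1e3,,,,
C0017C,1H-7,HPCS,26.6,"Pumiceous gravel, clast-supported",N.D.,0.0e0,N.D.,2.8e-6,+,1
C0017C,2H-1,HPCS,28.4,"Pumiceous gravel, clast-supported",1.9e4,9.6e3,,,+,5
C0017C,2H-2,HPCS,30.0,Sandy clay,N.D.,1.5e2,N.D.,7.2e-6,+,0
C0017D,1H-3,HPCS,63.6,"Pumiceous gravel, matrix-supported",N.D.,N.D.,4.0e-6,1.5e-5,+,0
C0017D,1H-5,HPCS,66.4,"Pumiceous gravel, clast-supported",N.D.,N.D.,4.4e-6,1.8e-6,,
C0017D,1H-6,HPCS,68.1,Volcaniclastic sand/sandstone,N.D.,N.D.,N.D.,1.4e-5,+,0
C0017D,2H-5,HPCS,74.9,Volcaniclastic mud/mudstone,N.D.,5.1e3,N.D.,3.6e-6,+,1
C0017D,6X-1,ESCS,95.0,Clay,,,N.D.,2.9e-6,+,0
C0017D,7H-4,HPCS,108.2,Silty clay,N.D.,7.0e3,2.2e-6,1.9e-6,+,0
C0017D,9X-8,ESCS,130.1,Clay,,,2.6e-6,3.8e-6,+,0
C0017D,10X-4,ESCS,136.1,Clay,,,1.2e-6,,,
C0017D,11X-1,ESCS,141.1,Silty clay,,,6.6e-6,7.4e-4,+,55
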