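compound_id,label,docking,dg_more,sigma_more,pose_bfes,dg_less,diff
CHEMBL257091,active,-8.8,-27.1,1.5,-27.1;-3.9;-10.8;-4.0;-4.0,-21.0,6.1
CHEMBL502121,active,-9.4,-25.1,2.0,-13.4;-8.7;-25.1;-14.6;-6.5,-19.1,6.0
CHEMBL260834,active,-8.7,-22.8,1.8,-12.6;-22.8;-13.0;-13.1;4.9,-17.9,4.9
CHEMBL502289,active,-9.2,-22.6,1.2,-22.2;0.4;-9.0;-1.4;-22.2,-22.3,0.3
CHEMBL1092147,active,-8.7,-21.9,1.1,-19.4;-21.9;-1.7;4.9;-14.9,-17.0,4.9
CHEMBL230245,active,-9.0,-21.3,1.9,-14.9;-17.8;-10.2;-21.3;-12.8,-19.0,2.3
CHEMBL595065,active,-8.5,-21.1,2.1,-18.5;-17.4;-20.6;6.5;-20.8,-18.8,2.3
CHEMBL571433,active,-9.6,-19.8,3.0,-4.1;-19.8;-10.2;-1.7;-7.3,-10.9,8.9
C01491960,decoy,-8.8,-18.2,1.7,-8.3;-10.3;-18.1;-3.4;-16.9,-13.7,4.5
CHEMBL404839,active,-9.3,-18.1,1.8,-8.4;-18.1;-12.2;-13.9;-15.3,-18.1,0.0
CHEMBL257645,active,-8.7,-17.1,1.5,-9.0;-8.2;-17.1;-14.9;-0.0,-15.9,1.2
CHEMBL500555,active,-8.6,-17.0,2.5,-17.0;-9.4;-10.6;3.5;-9.2,-17.0,0.0
C39631886,decoy,-8.5,-16.5,1.9,-6.1;-16.5;-11.5;-5.5;-7.8,-12.5,4.0
C39559755,decoy,-8.5,-15.4,1.3,-5.9;5.2;-15.4;-7.5;-4.0,-11.7,3.7
CHEMBL1092146,active,-8.6,-15.3,1.9,-13.2;-15.3;-12.6;1.9;-0.2,-14.7,0.6
C22874288,decoy,-8.8,-14.2,1.2,-14.2;-3.4;0.9;-5.8;-2.1,-9.6,4.6
CHEMBL595066,active,-8.6,-14.0,1.3,-14.0;-10.2;-2.1;-7.8;1.2,-13.5,0.5
C39674030,decoy,-8.8,-12.1,2.0,-3.9;1.3;-12.1;-10.0;0.5,-11.6,0.5
C28524322,decoy,-8.7,-11.8,1.7,-11.8;-5.7;-6.7;-3.9;-4.6,-11.6,0.2
CHEMBL517179,active,-8.9,-11.4,1.4,-11.4;-4.5;-3.4;-7.7;-0.6,-9.7,1.7
C39631541,decoy,-8.7,-10.4,1.8,-3.9;-10.4;2.8;-6.2;4.6,-9.0,1.4
C28706109,decoy,-9.0,-10.0,1.6,-5.7;6.4;-5.8;-10.0;-5.2,-5.8,4.2
C39674755,decoy,-8.6,-10.0,2.4,8.4;-1.3;1.0;0.3;-10.0,-6.4,3.6
C39669490,decoy,-8.6,-8.9,1.1,-2.9;-8.6;-2.6;-6.8;-8.2,-5.0,3.9
C35048276,decoy,-8.5,-8.6,1.4,-1.1;-8.6;-3.7;-3.1;-3.9,-6.7,1.9
C35750025,decoy,-8.8,-7.0,2.1,-7.0;6.3;2.4;1.6;2.9,-5.6,1.4
CHEMBL1092788,active,-8.7,-6.4,0.9,-4.9;-6.0;-5.8;-1.8;-4.8,-6.0,0.4
C40318643,decoy,-8.9,-5.0,1.3,-3.5;-2.0;-0.8;-2.8;-5.0,-4.7,0.3
C27260756,decoy,-8.9,-4.8,1.6,0.8;-4.8;-0.7;-1.0;-1.5,-2.6,2.2
C36064029,decoy,-8.8,-4.7,2.4,0.8;2.2;-2.4;0.2;-4.7,-4.1,0.6
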